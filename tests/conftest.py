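import numpy as np
import pandas as pd
import pytest

from sexarch.annotation import gene_lengths
from sexarch import expression as expr
from sexarch.synthetic import SimulationConfig, generate_annotation, generate_counts


@pytest.fixture(scope="session")
def default_config():
    return SimulationConfig(seed=7)


@pytest.fixture(scope="session")
def dataset(default_config):
    """One default synthetic dataset shared by read-only tests."""
    ann = generate_annotation(default_config)
    counts, samples, truth = generate_counts(ann, default_config)
    return {"config": default_config, "annotation": ann, "counts": counts,
            "samples": samples, "truth": truth}


@pytest.fixture(scope="session")
def calls_leg3(dataset):
    """Bias calls for leg 3 on the shared dataset (expensive, reused)."""
    counts, samples = dataset["counts"], dataset["samples"]
    ab = expr.compute_abundance(counts, gene_lengths(dataset["annotation"]))
    expressed = expr.filter_expressed(ab.fpkm, samples)
    de = expr.run_de_standin(counts, samples, ("sex", 3))
    calls = expr.call_sex_bias(de, expressed[3], leg=3)
    return expr.reassign_log2fc(calls), de, expressed


def toy_annotation(spacings, scaffold="s1", gene_len=1000):
    """Genes laid head-to-tail with the given start positions."""
    rows = []
    for i, start in enumerate(spacings):
        rows.append({"gene_id": f"g{i+1}", "scaffold": scaffold, "start": start,
                     "end": start + gene_len, "strand": "+"})
    return pd.DataFrame(rows)


def exact_mwu_two_sided(a, b):
    """Brute-force two-sided rank-sum p by enumerating all group splits."""
    from itertools import combinations
    from scipy.stats import rankdata

    pooled = np.concatenate([a, b])
    n1 = len(a)
    ranks = rankdata(pooled)
    u_obs = ranks[:n1].sum() - n1 * (n1 + 1) / 2
    us = []
    for combo in combinations(range(len(pooled)), n1):
        u = ranks[list(combo)].sum() - n1 * (n1 + 1) / 2
        us.append(u)
    us = np.asarray(us)
    eps = 1e-9
    p_ge = np.mean(us >= u_obs - eps)
    p_le = np.mean(us <= u_obs + eps)
    return min(1.0, 2 * min(p_ge, p_le))
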