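import numpy as np
import pandas as pd
import pytest

from mrscreen.harmonize import harmonized_from_arrays
from mrscreen.sumstats import CANONICAL_COLUMNS, SummaryStatsTable


def make_table(rows, trait_id="trait", trait_type="continuous"):
    """Build a SummaryStatsTable from a list of dicts with sensible defaults."""
    defaults = {
        "chrom": "1", "pos": 1000, "effect_allele": "A", "other_allele": "G",
        "eaf": 0.3, "beta": 0.1, "se": 0.02, "pval": 1e-6, "n": 10_000,
    }
    full = []
    for i, r in enumerate(rows):
        rec = {**defaults, "snp_id": f"rs{i + 1}", "pos": 1000 + 1000 * i, **r}
        full.append(rec)
    df = pd.DataFrame(full, columns=CANONICAL_COLUMNS)
    df["pos"] = df["pos"].astype(np.int64)
    df["n"] = df["n"].astype(np.int64)
    return SummaryStatsTable(trait_id, trait_type, df)


def random_harmonized_set(rng, n_snp, outcome_type="continuous"):
    """A random but internally consistent harmonized set for estimator tests."""
    gamma = rng.normal(0.1, 0.05, n_snp)
    gamma[np.abs(gamma) < 1e-3] = 0.05  # keep ratios well defined
    se_gamma = rng.uniform(0.005, 0.02, n_snp)
    Gamma = rng.normal(0.02, 0.02, n_snp)
    se_Gamma = rng.uniform(0.002, 0.02, n_snp)
    return harmonized_from_arrays(gamma, se_gamma, Gamma, se_Gamma,
                                  outcome_type=outcome_type)


@pytest.fixture
def rng():
    return np.random.default_rng(20240528)
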