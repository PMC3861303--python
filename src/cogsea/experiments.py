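"""Replicate-level studies of the pipeline's operating characteristics.

Two canned experiments, each one full pipeline run per replicate at the
default study conditions:

* null calibration — the target GWAS carries no shared signal
  (``shared_fraction = 0``); measures the fraction of candidate sets at
  nominal p <= 0.05 and how many sets end up both declared and
  mimic-validated (false discoveries of the whole procedure);
* recovery — the default shared-genetics conditions (15 of 25 causal genes
  shared, target non-centrality 12); measures whether the injected trait's
  top-25 candidate set is declared enriched and mimic-validated.
"""

from __future__ import annotations

import numpy as np

from .config import PipelineConfig, SimConfig
from .pipeline import run_full_pipeline, trait_labels

__all__ = ["null_calibration_replicate", "recovery_replicate", "replicate_seeds"]


def replicate_seeds(base_seed: int, n: int) -> list[int]:
    """n distinct master seeds derived from one base seed (all < 2^31)."""
    rng = np.random.default_rng(base_seed)
    return [int(s) for s in rng.integers(0, 2**31, size=n)]


def null_calibration_replicate(master_seed: int) -> dict:
    """One pipeline run with a signal-free target GWAS."""
    cfg = PipelineConfig(sim=SimConfig(master_seed=master_seed, shared_fraction=0.0))
    res = run_full_pipeline(cfg)
    e = res.enrichment
    finite = e["p_nominal"].notna()
    return {
        "frac_p_le_05": float((e.loc[finite, "p_nominal"] <= 0.05).mean()),
        "n_sets": int(finite.sum()),
        "n_hits": int((e.loc[finite, "p_nominal"] <= 0.05).sum()),
        "n_declared": int(e["enriched"].sum()),
        "n_validated": sum(1 for v in res.validations.values() if v["validated"]),
    }


def recovery_replicate(master_seed: int) -> dict:
    """One pipeline run at the default shared-genetics conditions."""
    cfg = PipelineConfig(sim=SimConfig(master_seed=master_seed))
    res = run_full_pipeline(cfg)
    target_set = f"{trait_labels(cfg.n_traits)[0]}-{cfg.set_build.thresholds[0]}"
    row = res.enrichment.set_index("set_name").loc[target_set]
    outcome = res.validations.get(target_set, {})
    declared = bool(row["enriched"])
    validated = bool(outcome.get("validated")) if declared else False
    return {
        "set": target_set,
        "p_nominal": float(row["p_nominal"]),
        "q_fdr_mean": float(row["q_fdr_mean"]),
        "declared": declared,
        "validated": validated,
        "recovered": declared and validated,
    }
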