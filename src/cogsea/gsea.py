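"""Weighted preranked gene-set enrichment with a permutation null.

The enrichment score (ES) is the signed extremum of a running sum along the
ranked gene list: at a set member at position i the sum rises by
|s_i|^w / sum over members of |s_j|^w, at a non-member it falls by
1 / (N - N_hits).  The null distribution comes from permuting gene labels
over the ranked positions (scores stay in place); permutations are shared
by all sets within a run, which is what the pooled FDR across sets assumes.
Nominal p and the normalized ES (NES) use the same-sign part of the null;
the FDR q pools the per-set normalized null ESs over every set tested
together.  Each analysis is repeated over independent runs and the mean and
SD of q across runs are reported, with declaration at p <= p_max and mean
q <= q_max, and mimic-set validation at the percentile rule.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._seeds import stage_seed
from .config import GseaConfig, ValidationConfig
from .containers import GeneSet, GeneSetCollection

__all__ = [
    "RankedList",
    "enrichment_score",
    "permutation_null",
    "nominal_p",
    "normalized_es",
    "fdr_q",
    "run_gsea",
    "mimic_validate",
]

MIN_EFFECTIVE_SIZE = 2  # minimum members found in the ranked list for run_gsea

# two running-sum extrema whose magnitudes agree to this relative tolerance
# are treated as tied (earliest position wins); mathematically exact ties
# otherwise resolve by float noise from the summation order
TIE_RTOL = 1e-9


@dataclass
class RankedList:
    """Array view of a ranked gene list (scores in rank order, descending)."""

    gene_ids: np.ndarray
    scores: np.ndarray

    @classmethod
    def from_frame(cls, ranked: pd.DataFrame) -> "RankedList":
        df = ranked.sort_values("rank") if "rank" in ranked.columns else ranked
        return cls(
            df["gene_id"].astype(str).to_numpy(),
            df["score"].to_numpy(dtype=float),
        )

    def __post_init__(self) -> None:
        if len(self.gene_ids) != len(self.scores):
            raise ValueError("gene_ids and scores length mismatch")
        self._index = {g: i for i, g in enumerate(self.gene_ids)}

    def __len__(self) -> int:
        return len(self.gene_ids)

    def member_indices(self, genes) -> np.ndarray:
        """Positions (0-based) of the genes present in the list, sorted."""
        idx = [self._index[g] for g in genes if g in self._index]
        return np.array(sorted(idx), dtype=np.int64)


def _as_ranked(ranked) -> RankedList:
    return ranked if isinstance(ranked, RankedList) else RankedList.from_frame(ranked)


def enrichment_score(
    ranked, gene_set, weight_exponent: float = 1.0
) -> tuple[float, np.ndarray, list[str]]:
    """ES, full running-sum profile and leading edge for one gene set.

    The ES is the running-sum value of largest magnitude (earliest position
    on ties).  The leading edge holds members at positions up to and
    including the extremum for positive ES, and strictly after it for
    negative ES.
    """
    rl = _as_ranked(ranked)
    genes = gene_set.genes if isinstance(gene_set, GeneSet) else tuple(gene_set)
    members = rl.member_indices(genes)
    N = len(rl)
    k = len(members)
    if k == 0:
        raise ValueError("no gene-set member appears in the ranked list")
    if k >= N:
        raise ValueError("gene set covers the whole ranked list (miss denominator is zero)")
    w = np.abs(rl.scores[members]) ** weight_exponent
    norm = w.sum()
    if norm <= 0:
        raise ValueError("all member scores are zero under the chosen weight")
    hit = np.zeros(N)
    hit[members] = w / norm
    miss = np.full(N, 1.0 / (N - k))
    miss[members] = 0.0
    profile = np.cumsum(hit - miss)
    absR = np.abs(profile)
    amax = float(absR.max())
    i_star = int(np.flatnonzero(absR >= amax * (1.0 - TIE_RTOL))[0])  # earliest tie
    es = float(profile[i_star])
    if es >= 0:
        leading = members[members <= i_star]
    else:
        leading = members[members > i_star]
    return es, profile, [str(rl.gene_ids[i]) for i in leading]


def _es_from_positions(sorted_pos: np.ndarray, weights: np.ndarray, N: int) -> np.ndarray:
    """Vectorized ES from sorted member positions (event-based, O(k)).

    ``sorted_pos`` is (m, k), 0-based and ascending per row; ``weights`` the
    matching |score|^w values.  The running sum attains its maximum just
    after a hit and its minimum just before a hit, so only those 2k
    candidates are inspected; ties in |ES| resolve to the earliest position,
    matching :func:`enrichment_score` exactly.
    """
    m, k = sorted_pos.shape
    d = 1.0 / (N - k)
    wsum = weights.sum(axis=1, keepdims=True)
    W = np.cumsum(weights, axis=1) / wsum
    j = np.arange(k)
    misses_before = sorted_pos - j  # misses among positions 0..pos[j]
    hit_vals = W - misses_before * d  # profile value at each hit position
    before_vals = hit_vals - weights / wsum  # profile just before each hit

    arg_hi = np.argmax(hit_vals, axis=1)
    rows = np.arange(m)
    hi = hit_vals[rows, arg_hi]
    pos_hi = sorted_pos[rows, arg_hi]

    # a "before" candidate at position pos[j]-1 is invalid when pos[j] == 0
    invalid = sorted_pos == 0
    bv = np.where(invalid, np.inf, before_vals)
    arg_lo = np.argmin(bv, axis=1)
    lo = bv[rows, arg_lo]
    pos_lo = sorted_pos[rows, arg_lo] - 1
    no_lo = ~np.isfinite(lo)
    lo = np.where(no_lo, 0.0, lo)

    tie = np.abs(lo + hi) <= TIE_RTOL * np.maximum(hi, -lo)
    take_lo = ((-lo > hi) & ~tie) | (tie & (pos_lo < pos_hi) & (lo < 0))
    take_lo &= ~no_lo
    return np.where(take_lo, lo, hi)


try:  # compiled kernel for the permutation null; the numpy path is identical
    import numba

    @numba.njit(cache=False)
    def _es_kernel(pos, w, N):  # pragma: no cover - exercised via permutation_null
        m, k = pos.shape
        out = np.empty(m)
        d = 1.0 / (N - k)
        for i in range(m):
            wsum = 0.0
            for j in range(k):
                wsum += w[i, j]
            run = 0.0
            hi = -np.inf
            hi_pos = 0
            lo = np.inf
            lo_pos = 0
            for j in range(k):
                p = pos[i, j]
                before = run - (p - j) * d
                if p > 0 and before < lo:
                    lo = before
                    lo_pos = p - 1
                run += w[i, j] / wsum
                hit = run - (p - j) * d
                if hit > hi:
                    hi = hit
                    hi_pos = p
            if lo == np.inf:
                out[i] = hi
            else:
                big = hi if hi > -lo else -lo
                tie = abs(lo + hi) <= 1e-9 * big
                if ((-lo > hi) and not tie) or (tie and lo < 0 and lo_pos < hi_pos):
                    out[i] = lo
                else:
                    out[i] = hi
        return out

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    _HAVE_NUMBA = False


def _permutation_matrix(rng: np.random.Generator, n_perm: int, N: int) -> np.ndarray:
    """(n_perm, N) independent uniform permutations of 0..N-1; column g is
    the permuted position of gene g."""
    return np.argsort(rng.random((n_perm, N)), axis=1).astype(np.int32)


def permutation_null(
    ranked,
    gene_set,
    config: GseaConfig | None = None,
    seed=None,
    perms: np.ndarray | None = None,
) -> np.ndarray:
    """Null ES sample from gene-label permutations of the ranked list.

    Scores stay at their positions; member labels land at uniformly random
    positions without replacement.  ``perms`` allows sharing one
    permutation matrix across the sets of a run.
    """
    config = config or GseaConfig()
    rl = _as_ranked(ranked)
    genes = gene_set.genes if isinstance(gene_set, GeneSet) else tuple(gene_set)
    members = rl.member_indices(genes)
    N = len(rl)
    if len(members) == 0 or len(members) >= N:
        raise ValueError("degenerate gene set for permutation null")
    if perms is None:
        rng = np.random.default_rng(config.seed if seed is None else seed)
        perms = _permutation_matrix(rng, config.n_permutations, N)
    pos = np.sort(perms[:, members], axis=1)
    weights = np.abs(rl.scores[pos])
    if config.weight_exponent != 1.0:
        weights **= config.weight_exponent
    if _HAVE_NUMBA:
        return _es_kernel(pos.astype(np.int64), weights, N)
    return _es_from_positions(pos, weights, N)


def nominal_p(es: float, null_sample: np.ndarray) -> tuple[float, bool]:
    """One-sided same-sign permutation p-value.

    For es >= 0, p = #(null >= es) / #(null >= 0); mirrored for es < 0.  A
    zero numerator reports p = 0 with the below-resolution flag set
    (meaning "< 1 / n_permutations").  Raises when no same-sign null values
    exist.
    """
    null_sample = np.asarray(null_sample, dtype=float)
    if null_sample.size == 0:
        raise ValueError("empty null sample")
    if es >= 0:
        denom = int((null_sample >= 0).sum())
        numer = int((null_sample >= es).sum())
    else:
        denom = int((null_sample < 0).sum())
        numer = int((null_sample <= es).sum())
    if denom == 0:
        raise ValueError("no same-sign null values; p not computable")
    p = numer / denom
    return (0.0, True) if numer == 0 else (float(p), False)


def normalized_es(es: float, null_sample: np.ndarray) -> float:
    """ES divided by the magnitude of the mean same-sign null ES (sign of
    the observed ES preserved)."""
    null_sample = np.asarray(null_sample, dtype=float)
    same = null_sample[null_sample >= 0] if es >= 0 else null_sample[null_sample < 0]
    if same.size == 0:
        raise ValueError("no same-sign null values; NES not computable")
    denom = abs(float(same.mean()))
    if denom == 0:
        raise ValueError("mean same-sign null ES is zero; NES not computable")
    return float(es / denom)


def fdr_q(observed_nes: np.ndarray, null_nes_pool: np.ndarray) -> np.ndarray:
    """FDR q per set from the pooled normalized permutation ESs.

    For nes >= 0:  q = [#(pool >= nes)/#(pool >= 0)] / [#(obs >= nes)/#(obs >= 0)],
    clipped to [0, 1]; mirrored for negative nes.
    """
    obs = np.asarray(observed_nes, dtype=float)
    pool = np.asarray(null_nes_pool, dtype=float)
    if pool.size == 0 or obs.size == 0:
        raise ValueError("empty NES pool")
    pool_pos = np.sort(pool[pool >= 0])
    pool_neg = np.sort(pool[pool < 0])
    obs_pos = np.sort(obs[obs >= 0])
    obs_neg = np.sort(obs[obs < 0])
    q = np.empty_like(obs)
    for i, nes in enumerate(obs):
        if nes >= 0:
            if pool_pos.size == 0:
                q[i] = np.nan
                continue
            null_frac = (pool_pos.size - np.searchsorted(pool_pos, nes, side="left")) / pool_pos.size
            obs_frac = (obs_pos.size - np.searchsorted(obs_pos, nes, side="left")) / obs_pos.size
        else:
            if pool_neg.size == 0:
                q[i] = np.nan
                continue
            null_frac = np.searchsorted(pool_neg, nes, side="right") / pool_neg.size
            obs_frac = np.searchsorted(obs_neg, nes, side="right") / obs_neg.size
        q[i] = min(1.0, null_frac / obs_frac) if obs_frac > 0 else np.nan
    return q


def run_gsea(
    ranked, collection: GeneSetCollection, config: GseaConfig | None = None
) -> pd.DataFrame:
    """Full multi-set preranked GSEA report.

    Per set: run-invariant ES and leading edge; NES and nominal p from the
    first run; FDR q mean and SD over ``n_runs`` runs (each with its own
    derived permutation seed); rank R by ascending mean q (ties by p, then
    name); ``enriched`` iff p <= p_max and mean q <= q_max.  Members absent
    from the ranked list are dropped (``effective_size`` records the rest);
    sets with fewer than two effective members, or covering the whole list,
    are reported with NaN statistics.  Deterministic given ``config.seed``.
    """
    config = config or GseaConfig()
    if len(collection) == 0:
        raise ValueError("empty gene-set collection")
    rl = _as_ranked(ranked)
    N = len(rl)

    sets = []
    for s in collection:
        members = rl.member_indices(s.genes)
        w = np.abs(rl.scores[members]) ** config.weight_exponent if members.size else np.array([])
        usable = MIN_EFFECTIVE_SIZE <= members.size < N and w.sum() > 0
        sets.append((s, members, usable))
    if not any(u for _, _, u in sets):
        raise ValueError("every gene set is degenerate on this ranked list")

    es_arr = np.full(len(sets), np.nan)
    leading: list[list[str]] = [[] for _ in sets]
    for i, (s, members, usable) in enumerate(sets):
        if usable:
            es_arr[i], _, leading[i] = enrichment_score(rl, s, config.weight_exponent)

    usable_idx = [i for i, (_, _, u) in enumerate(sets) if u]
    q_runs = np.full((config.n_runs, len(sets)), np.nan)
    p_first = np.full(len(sets), np.nan)
    below_res = np.zeros(len(sets), dtype=bool)
    nes_first = np.full(len(sets), np.nan)

    for run in range(config.n_runs):
        rng = np.random.default_rng(stage_seed(config.seed, f"gsea-run{run + 1}"))
        perms = _permutation_matrix(rng, config.n_permutations, N)
        nes_run = np.full(len(sets), np.nan)
        null_nes_pool: list[np.ndarray] = []
        null_by_set: dict[int, np.ndarray] = {}
        for i in usable_idx:
            s, members, _ = sets[i]
            null_es = permutation_null(rl, s, config, perms=perms)
            null_by_set[i] = null_es
            pos = null_es[null_es >= 0]
            neg = null_es[null_es < 0]
            parts = []
            if pos.size:
                parts.append(pos / pos.mean())
            if neg.size:
                parts.append(-(neg / neg.mean()))  # sign preserved after normalizing
            null_nes_pool.append(np.concatenate(parts))
            try:
                nes_run[i] = normalized_es(es_arr[i], null_es)
            except ValueError:
                nes_run[i] = np.nan
        pool = np.concatenate(null_nes_pool)
        valid = [i for i in usable_idx if np.isfinite(nes_run[i])]
        if valid:
            q_vals = fdr_q(nes_run[valid], pool)
            q_runs[run, valid] = q_vals
        if run == 0:
            nes_first = nes_run
            for i in valid:
                try:
                    p_first[i], below_res[i] = nominal_p(es_arr[i], null_by_set[i])
                except ValueError:
                    pass

    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        q_mean = np.nanmean(q_runs, axis=0)
        q_sd = np.nanstd(q_runs, axis=0, ddof=1) if config.n_runs > 1 else np.zeros(len(sets))

    report = pd.DataFrame(
        {
            "set_name": [s.name for s, _, _ in sets],
            "set_size": [len(s) for s, _, _ in sets],
            "effective_size": [int(m.size) for _, m, _ in sets],
            "es": es_arr,
            "nes": nes_first,
            "p_nominal": p_first,
            "p_below_resolution": below_res,
            "q_fdr_mean": q_mean,
            "q_fdr_sd": q_sd,
            "leading_edge": [";".join(le) for le in leading],
        }
    )
    order = report.sort_values(
        ["q_fdr_mean", "p_nominal", "set_name"], ascending=True, kind="stable", na_position="last"
    ).index
    rank_R = np.empty(len(report), dtype=int)
    rank_R[order] = np.arange(1, len(report) + 1)
    report["rank_R"] = rank_R
    report["enriched"] = (
        np.isfinite(report["p_nominal"])
        & (report["p_nominal"] <= config.p_max)
        & np.isfinite(report["q_fdr_mean"])
        & (report["q_fdr_mean"] <= config.q_max)
    )
    return report


def mimic_validate(
    candidate_nes: float,
    mimic_nes,
    config: ValidationConfig | None = None,
) -> tuple[bool, int]:
    """Validate a candidate against its mimic random sets.

    Validated iff the candidate NES strictly exceeds at least
    ``percentile_rule`` of the ``n_mimic`` mimic NES values (the required
    count scales proportionally when non-computable mimics are excluded).
    Returns ``(validated, count_exceeded)``.
    """
    config = config or ValidationConfig()
    mimic_nes = np.asarray(mimic_nes, dtype=float)
    if mimic_nes.size != config.n_mimic:
        raise ValueError(f"expected {config.n_mimic} mimic NES values, got {mimic_nes.size}")
    valid = mimic_nes[np.isfinite(mimic_nes)]
    if valid.size < mimic_nes.size:
        import warnings

        warnings.warn(
            f"{mimic_nes.size - valid.size} mimic sets had no computable NES and were excluded",
            stacklevel=2,
        )
    if valid.size == 0:
        raise ValueError("no computable mimic NES values")
    exceeded = int((candidate_nes > valid).sum())
    required = config.percentile_rule / config.n_mimic * valid.size
    return exceeded >= np.ceil(required - 1e-9), exceeded
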