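"""Resampling null models for the disruption screen's headline comparisons.

Two nulls are implemented:

* an allele-frequency-matched draw null for "are the disrupting SNPs more
  often eQTLs than random SNPs?" — random SNP sets are matched to the
  observed set's minor-allele-frequency (MAF) spectrum bin by bin, the
  number of eQTL-significant members is recorded per simulation, and the
  observation is summarized as Z = (observed - null mean) / null sd with
  P = Phi(-|Z|);

* a per-TF count null for "does one TF soak up more disrupting SNPs than
  chance?" — fixed-size SNP subsets are drawn without replacement from the
  full disrupting-SNP pool and per-TF counts tallied, with an add-one
  empirical p-value (r + 1) / (n_sims + 1).

Within a MAF bin a matched draw is uniform without replacement, so the
per-bin count of eQTL-flagged members in a simulated set is hypergeometric;
the null counts are sampled per bin from that exact law, which is identical
in distribution to materializing the matched SNP draw and counting, and
much faster. ``maf_matched_sample`` still materializes explicit draws.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import InfeasibleMatchingError

DEFAULT_BIN_WIDTH = 0.05
MAF_MAX = 0.5


@dataclass(frozen=True)
class SNPPool:
    """The sampling universe: snp_id, MAF, eQTL-significance flag and an
    optional disrupted-TF label per SNP."""

    snp_ids: np.ndarray
    mafs: np.ndarray
    eqtl_flags: np.ndarray
    tf_labels: np.ndarray | None = None

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "SNPPool":
        ids = df["snp_id"].to_numpy(dtype=object)
        if len(set(ids)) != len(ids):
            raise ValueError("SNP pool snp_ids must be unique")
        mafs = df["maf"].to_numpy(dtype=float)
        if ((mafs <= 0) | (mafs > MAF_MAX)).any():
            raise ValueError("pool MAFs must lie in (0, 0.5]")
        flags = df["eqtl_flag"].to_numpy()
        flags = np.asarray(flags, dtype=bool)
        tf = None
        if "tf" in df.columns and df["tf"].notna().any():
            tf = df["tf"].to_numpy(dtype=object)
        return cls(snp_ids=ids, mafs=mafs, eqtl_flags=flags, tf_labels=tf)

    def __len__(self) -> int:
        return len(self.snp_ids)


@dataclass
class EnrichmentResult:
    observed: int
    null_mean: float
    null_sd: float
    z: float
    p: float
    n_sims: int
    seed: int
    null_counts: np.ndarray = field(repr=False, default=None)

    def to_dict(self) -> dict:
        return {
            "observed": self.observed,
            "null_mean": self.null_mean,
            "null_sd": self.null_sd,
            "z": self.z,
            "p": self.p,
            "n_sims": self.n_sims,
            "seed": self.seed,
        }


def maf_bin_index(mafs: np.ndarray, bin_width: float = DEFAULT_BIN_WIDTH) -> np.ndarray:
    """Bin MAFs on (0, 0.5] into floor(maf / width) bins, with the closed
    right edge folded into the last bin."""
    n_bins = int(round(MAF_MAX / bin_width))
    idx = np.floor(np.asarray(mafs, dtype=float) / bin_width).astype(int)
    return np.minimum(idx, n_bins - 1)


def maf_matched_sample(
    pool: SNPPool,
    template_mafs,
    bin_width: float = DEFAULT_BIN_WIDTH,
    rng_seed: int | np.random.Generator = 0,
) -> list[str]:
    """Draw one pool SNP per template SNP, uniformly without replacement
    within the template SNP's MAF bin. Deterministic given the seed."""
    rng = (
        rng_seed
        if isinstance(rng_seed, np.random.Generator)
        else np.random.default_rng(rng_seed)
    )
    template_bins = maf_bin_index(np.asarray(template_mafs, dtype=float), bin_width)
    pool_bins = maf_bin_index(pool.mafs, bin_width)
    need = np.bincount(template_bins, minlength=pool_bins.max() + 2)
    chosen: list[str] = []
    short_bins = []
    for b in np.nonzero(need)[0]:
        candidates = np.nonzero(pool_bins == b)[0]
        if len(candidates) < need[b]:
            short_bins.append((int(b), int(need[b]), len(candidates)))
            continue
        take = rng.choice(candidates, size=int(need[b]), replace=False)
        chosen.extend(pool.snp_ids[i] for i in np.sort(take))
    if short_bins:
        desc = ", ".join(
            f"bin [{b * bin_width:.2f}, {(b + 1) * bin_width:.2f}): "
            f"need {k}, have {n}"
            for b, k, n in short_bins
        )
        raise InfeasibleMatchingError(f"MAF matching infeasible: {desc}", bins=short_bins)
    return chosen


def _null_eqtl_counts(
    pool: SNPPool,
    template_bins: np.ndarray,
    n_sims: int,
    bin_width: float,
    rng: np.random.Generator,
    exclude_idx: np.ndarray | None = None,
) -> np.ndarray:
    """Null vector of eQTL-flag counts across simulated MAF-matched sets,
    drawn per bin from the exact hypergeometric law of a without-replacement
    matched draw."""
    pool_bins = maf_bin_index(pool.mafs, bin_width)
    flags = pool.eqtl_flags.copy()
    mask = np.ones(len(pool), dtype=bool)
    if exclude_idx is not None:
        mask[exclude_idx] = False
    need = np.bincount(template_bins, minlength=pool_bins.max() + 2)
    counts = np.zeros(n_sims, dtype=np.int64)
    short_bins = []
    for b in np.nonzero(need)[0]:
        in_bin = mask & (pool_bins == b)
        n_bin = int(in_bin.sum())
        k = int(need[b])
        if n_bin < k:
            short_bins.append((int(b), k, n_bin))
            continue
        n_good = int(flags[in_bin].sum())
        counts += rng.hypergeometric(n_good, n_bin - n_good, k, size=n_sims)
    if short_bins:
        desc = ", ".join(
            f"bin [{b * bin_width:.2f}, {(b + 1) * bin_width:.2f}): need {k}, have {n}"
            for b, k, n in short_bins
        )
        raise InfeasibleMatchingError(f"MAF matching infeasible: {desc}", bins=short_bins)
    return counts


def eqtl_enrichment_z(
    pool: SNPPool,
    observed_set,
    n_sims: int = 10_000,
    bin_width: float = DEFAULT_BIN_WIDTH,
    seed: int = 0,
    observed_mafs=None,
    observed_count: int | None = None,
    exclude_observed: bool = False,
    two_tailed: bool = False,
) -> EnrichmentResult:
    """Z test of the observed eQTL-significant count against MAF-matched
    random draws: Z = (observed - null mean) / null sd, P = Phi(-|Z|)
    (doubled when two_tailed). Raises on n_sims < 100 or a degenerate null.

    When the observed SNPs are not pool members, pass ``observed_mafs`` (for
    the matching template) and ``observed_count`` (their eQTL-significant
    count measured externally).
    """
    if n_sims < 100:
        raise ValueError("n_sims must be >= 100 for a usable null")
    observed_set = list(observed_set)
    id_to_idx = {s: i for i, s in enumerate(pool.snp_ids)}
    obs_idx = np.array([id_to_idx[s] for s in observed_set if s in id_to_idx], dtype=int)
    if observed_mafs is None:
        if len(obs_idx) != len(observed_set):
            missing = [s for s in observed_set if s not in id_to_idx]
            raise ValueError(
                f"{len(missing)} observed SNPs absent from pool and no "
                f"observed_mafs given (e.g. {missing[:3]})"
            )
        template_mafs = pool.mafs[obs_idx]
    else:
        template_mafs = np.asarray(observed_mafs, dtype=float)
    observed = (
        int(observed_count)
        if observed_count is not None
        else int(pool.eqtl_flags[obs_idx].sum())
    )
    rng = np.random.default_rng(seed)
    null_counts = _null_eqtl_counts(
        pool,
        maf_bin_index(template_mafs, bin_width),
        n_sims,
        bin_width,
        rng,
        exclude_idx=obs_idx if exclude_observed else None,
    )
    null_mean = float(null_counts.mean())
    null_sd = float(null_counts.std(ddof=0))
    if null_sd == 0:
        return EnrichmentResult(
            observed=observed,
            null_mean=null_mean,
            null_sd=0.0,
            z=float("nan"),
            p=float("nan"),
            n_sims=n_sims,
            seed=seed,
            null_counts=null_counts,
        )
    z = (observed - null_mean) / null_sd
    p = float(stats.norm.sf(abs(z)))
    if two_tailed:
        p = min(1.0, 2 * p)
    return EnrichmentResult(
        observed=observed,
        null_mean=null_mean,
        null_sd=null_sd,
        z=float(z),
        p=p,
        n_sims=n_sims,
        seed=seed,
        null_counts=null_counts,
    )


@dataclass(frozen=True)
class TFNullResult:
    tf: str
    observed: int
    null_mean: float
    null_sd: float
    empirical_p: float


def tf_count_null(
    pool_tf,
    m: int,
    observed_counts: dict[str, int],
    n_sims: int = 1000,
    seed: int = 0,
) -> dict[str, TFNullResult]:
    """Per-TF disruption-count null: draw m SNPs without replacement from the
    labelled pool n_sims times, tally counts per TF, and report mean, sd and
    the add-one empirical p-value P(count >= observed).

    ``pool_tf`` is an iterable of (snp_id, tf_label) with one label per SNP,
    or a DataFrame with snp_id/tf columns.
    """
    if isinstance(pool_tf, pd.DataFrame):
        labels = pool_tf["tf"].to_numpy(dtype=object)
    else:
        labels = np.array([tf for _, tf in pool_tf], dtype=object)
    if m > len(labels):
        raise ValueError(f"cannot sample {m} SNPs from a pool of {len(labels)}")
    tfs = sorted(set(labels) | set(observed_counts))
    tf_index = {tf: i for i, tf in enumerate(tfs)}
    colors = np.zeros(len(tfs), dtype=np.int64)
    for lab in labels:
        colors[tf_index[lab]] += 1
    rng = np.random.default_rng(seed)
    draws = rng.multivariate_hypergeometric(colors, m, size=n_sims)  # (n_sims, n_tf)
    out: dict[str, TFNullResult] = {}
    for tf in tfs:
        col = draws[:, tf_index[tf]]
        obs = int(observed_counts.get(tf, 0))
        r = int((col >= obs).sum())
        out[tf] = TFNullResult(
            tf=tf,
            observed=obs,
            null_mean=float(col.mean()),
            null_sd=float(col.std(ddof=0)),
            empirical_p=(r + 1) / (n_sims + 1),
        )
    return out


def tf_null_to_frame(results: dict[str, TFNullResult]) -> pd.DataFrame:
    rows = [
        {
            "tf": r.tf,
            "observed": r.observed,
            "null_mean": r.null_mean,
            "null_sd": r.null_sd,
            "empirical_p": r.empirical_p,
        }
        for r in sorted(results.values(), key=lambda r: r.tf)
    ]
    return pd.DataFrame(rows, columns=["tf", "observed", "null_mean", "null_sd", "empirical_p"])
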