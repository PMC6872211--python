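"""Circuit-sampling bias statistics.

Quantifies whether the two collicular output circuits (colliculo-
parabigeminal, "Pbg", and colliculo-pulvinar, "LP") sample ganglion cell
types differently.  For each cell type (cluster):

* the selectivity index SI = (%LP - %Pbg) / (%LP + %Pbg), where the
  percentages are each cluster's share of its circuit's classified cells;
  0 means equal sampling, +1/-1 unique sampling by LP/Pbg;
* a retina-level bootstrap (resampling retinas with replacement within
  each circuit) gives a two-sided p-value and a 2.5-97.5% interval for SI;
* a pooled two-proportion z-test compares the two binomial proportions;
* Benjamini-Hochberg FDR correction is applied separately to the bootstrap
  family and to the z-test family;
* only clusters holding at least 1% of all classified cells are included.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .core import CIRCUITS, InvalidSpecError, UndefinedSelectivityError, rng_stream

_BOOT_STREAM = 29


def selectivity_index(pct_lp: float, pct_pbg: float) -> float:
    """SI = (%LP - %Pbg) / (%LP + %Pbg); antisymmetric, in [-1, 1]."""
    if pct_lp < 0 or pct_pbg < 0:
        raise InvalidSpecError("percentages must be non-negative")
    total = pct_lp + pct_pbg
    if total == 0:
        raise UndefinedSelectivityError("cluster absent from both circuits")
    return (pct_lp - pct_pbg) / total


def include_clusters(sample: pd.DataFrame, min_fraction: float = 0.01) -> list[str]:
    """Clusters whose pooled share of all cells is >= ``min_fraction``."""
    totals = sample.groupby("cluster")["count"].sum()
    grand = totals.sum()
    if grand <= 0:
        raise InvalidSpecError("retina sample contains no cells")
    return sorted(totals.index[totals / grand >= min_fraction])


def two_proportion_ztest(k1: int, n1: int, k2: int, n2: int) -> tuple[float, float, bool]:
    """Pooled two-proportion z-test, two-sided, no continuity correction.

    Returns (z, p, degenerate).  When the pooled proportion is 0 or 1 the
    test statistic is undefined; p = 1 is returned with the degenerate
    flag set.
    """
    if not (0 <= k1 <= n1 and 0 <= k2 <= n2) or n1 <= 0 or n2 <= 0:
        raise InvalidSpecError("need 0 <= k <= n and n > 0 for both samples")
    pooled = (k1 + k2) / (n1 + n2)
    if pooled in (0.0, 1.0):
        return 0.0, 1.0, True
    se = np.sqrt(pooled * (1.0 - pooled) * (1.0 / n1 + 1.0 / n2))
    z = (k1 / n1 - k2 / n2) / se
    p = 2.0 * (1.0 - stats.norm.cdf(abs(z)))
    return float(z), float(p), False


def fdr_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)):
        raise InvalidSpecError("p-values must be in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def _count_matrices(sample: pd.DataFrame, clusters: list[str]) -> dict[str, np.ndarray]:
    """Per-circuit (n_retinas, n_clusters) count matrices."""
    out = {}
    for circuit in CIRCUITS:
        sub = sample[sample["circuit"] == circuit]
        if sub.empty:
            raise InvalidSpecError(f"no retinas for circuit {circuit}")
        pivot = (
            sub.pivot_table(index="retina_id", columns="cluster", values="count",
                            aggfunc="sum", fill_value=0)
            .reindex(columns=clusters, fill_value=0)
        )
        out[circuit] = pivot.to_numpy(dtype=float)
    return out


@dataclass
class BootstrapResult:
    clusters: list[str]
    si_observed: np.ndarray
    p_values: np.ndarray
    interval_low: np.ndarray
    interval_high: np.ndarray
    n_dropped: np.ndarray  # replicates with undefined SI, per cluster
    n_boot: int
    seed: int


def bootstrap_bias(
    sample: pd.DataFrame,
    n_boot: int = 10_000,
    seed: int = 0,
    clusters: list[str] | None = None,
) -> BootstrapResult:
    """Retina-level bootstrap of the per-cluster selectivity index.

    Each replicate resamples retinas with replacement within each circuit
    (preserving the per-circuit retina counts), recomputes every cluster's
    SI from the pooled resampled counts, and the two-sided p-value is
    2 x min(fraction <= 0, fraction >= 0) with the add-one correction
    p >= 1/(n_boot + 1).  Replicates where a cluster vanishes from both
    circuits contribute no SI for that cluster and are counted as dropped.
    """
    if clusters is None:
        clusters = sorted(sample["cluster"].unique())
    mats = _count_matrices(sample, clusters)
    for circuit, m in mats.items():
        if m.shape[0] < 2:
            raise InvalidSpecError(f"bootstrap needs >= 2 retinas per circuit ({circuit})")
    rng = rng_stream(seed, _BOOT_STREAM)

    def si_from_counts(lp_counts: np.ndarray, pbg_counts: np.ndarray) -> np.ndarray:
        # rows: replicates, columns: clusters; percentages within circuit
        lp_tot = lp_counts.sum(axis=1, keepdims=True)
        pbg_tot = pbg_counts.sum(axis=1, keepdims=True)
        with np.errstate(invalid="ignore", divide="ignore"):
            pct_lp = 100.0 * lp_counts / lp_tot
            pct_pbg = 100.0 * pbg_counts / pbg_tot
            si = (pct_lp - pct_pbg) / (pct_lp + pct_pbg)
        return si

    obs = si_from_counts(
        mats["LP"].sum(axis=0, keepdims=True), mats["Pbg"].sum(axis=0, keepdims=True)
    )[0]

    idx_lp = rng.integers(0, mats["LP"].shape[0], size=(n_boot, mats["LP"].shape[0]))
    idx_pbg = rng.integers(0, mats["Pbg"].shape[0], size=(n_boot, mats["Pbg"].shape[0]))
    lp_counts = mats["LP"][idx_lp].sum(axis=1)
    pbg_counts = mats["Pbg"][idx_pbg].sum(axis=1)
    si = si_from_counts(lp_counts, pbg_counts)  # NaN where cluster absent from both

    n_clusters = len(clusters)
    p = np.empty(n_clusters)
    lo = np.empty(n_clusters)
    hi = np.empty(n_clusters)
    dropped = np.zeros(n_clusters, dtype=int)
    for j in range(n_clusters):
        col = si[:, j]
        valid = col[~np.isnan(col)]
        dropped[j] = n_boot - valid.size
        if valid.size == 0:
            p[j] = 1.0
            lo[j] = hi[j] = np.nan
            continue
        frac_le = np.count_nonzero(valid <= 0) / valid.size
        frac_ge = np.count_nonzero(valid >= 0) / valid.size
        p[j] = min(1.0, max(2.0 * min(frac_le, frac_ge), 1.0 / (valid.size + 1)))
        lo[j] = np.percentile(valid, 2.5)
        hi[j] = np.percentile(valid, 97.5)
    return BootstrapResult(
        clusters=list(clusters), si_observed=obs, p_values=p,
        interval_low=lo, interval_high=hi, n_dropped=dropped,
        n_boot=n_boot, seed=seed,
    )


def bias_table(
    sample: pd.DataFrame,
    n_boot: int = 10_000,
    seed: int = 0,
    min_fraction: float = 0.01,
) -> pd.DataFrame:
    """Full per-cluster bias analysis.

    Returns a frame with per-cluster percentages, SI, bootstrap p and
    2.5-97.5% interval, two-proportion z-test p, FDR-adjusted p-values
    (computed separately per test family over the included clusters), and
    the >= 1% inclusion flag.
    """
    all_clusters = sorted(sample["cluster"].unique())
    included = set(include_clusters(sample, min_fraction))
    totals = sample.groupby(["circuit", "cluster"])["count"].sum().unstack(fill_value=0)
    n_lp = int(totals.loc["LP"].sum()) if "LP" in totals.index else 0
    n_pbg = int(totals.loc["Pbg"].sum()) if "Pbg" in totals.index else 0
    if n_lp == 0 or n_pbg == 0:
        raise InvalidSpecError("both circuits need classified cells")

    boot = bootstrap_bias(sample, n_boot=n_boot, seed=seed, clusters=all_clusters)
    rows = []
    for j, cluster in enumerate(all_clusters):
        k_lp = int(totals.loc["LP", cluster]) if cluster in totals.columns else 0
        k_pbg = int(totals.loc["Pbg", cluster]) if cluster in totals.columns else 0
        pct_lp = 100.0 * k_lp / n_lp
        pct_pbg = 100.0 * k_pbg / n_pbg
        si = selectivity_index(pct_lp, pct_pbg) if (pct_lp + pct_pbg) > 0 else np.nan
        z, p_z, degenerate = two_proportion_ztest(k_lp, n_lp, k_pbg, n_pbg)
        rows.append({
            "cluster": cluster,
            "pct_lp": pct_lp,
            "pct_pbg": pct_pbg,
            "selectivity_index": si,
            "boot_p": boot.p_values[j],
            "boot_low": boot.interval_low[j],
            "boot_high": boot.interval_high[j],
            "z": z,
            "ztest_p": p_z,
            "ztest_degenerate": degenerate,
            "included": cluster in included,
        })
    table = pd.DataFrame(rows)
    mask = table["included"].to_numpy()
    for col, adj in (("boot_p", "boot_p_fdr"), ("ztest_p", "ztest_p_fdr")):
        adjusted = np.full(len(table), np.nan)
        if mask.any():
            adjusted[mask] = fdr_adjust(table.loc[mask, col].to_numpy())
        table[adj] = adjusted
    return table
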