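"""Permutation FDR threshold determination and QTL power simulation.

The genome-wide significance cutoff is chosen empirically: each spot's
intensities are shuffled over the strains (breaking all genotype-
phenotype association while keeping every marginal distribution), the
full scan is re-run, and the number of spots that would be discovered at
a candidate cutoff t in permuted data (FDS, averaged over permutations)
is compared with the number discovered in the observed data (RDS).  The
selected threshold is the smallest t whose estimated FDR
``(m0/m) * FDS(t) / RDS(t)`` does not exceed the target q.

Power is assessed by planting single-marker QTL of known explained
variance on the real genetic map, adding standard-normal noise, and
re-scanning: an effect with allelic size a (in noise-SD units) at a
balanced marker explains ``R^2 = 0.25 a^2 / (0.25 a^2 + 1)`` of the
variance, so a peak size of 1 corresponds to 20% explained variation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .containers import ExpressionMatrix, GenotypeMatrix, P1
from .mapping import ScanMatrix, _ci_bounds, scan


@dataclass
class ThresholdResult:
    """Permutation FDR curves and the selected genome-wide cutoff."""

    q: float
    n_perm: int
    grid: np.ndarray  # candidate -log10(p) cutoffs, ascending
    rds: np.ndarray  # real discoveries (spots) at each cutoff
    fds: np.ndarray  # mean permutation discoveries at each cutoff
    m: int  # number of spots tested
    m0_ratio: float
    log_m_correction: str
    threshold: float | None

    @property
    def fdr(self) -> np.ndarray:
        with np.errstate(divide="ignore", invalid="ignore"):
            est = self.m0_ratio * self.fds / self.rds
        if self.log_m_correction == "multiply":
            est = est * np.log(self.m)
        elif self.log_m_correction == "divide":
            est = est / np.log(self.m)
        return est

    def curve_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"cutoff": self.grid, "RDS": self.rds, "FDS": self.fds, "FDR": self.fdr}
        )


def permutation_threshold(
    expression: ExpressionMatrix,
    genotypes: GenotypeMatrix,
    q: float = 0.1,
    n_perm: int = 10,
    seed: int | None = None,
    m0_ratio: float = 1.0,
    log_m_correction: str = "none",
) -> ThresholdResult:
    """Select the genome-wide -log10(p) cutoff by permutation FDR.

    Each permutation shuffles every spot's values independently over the
    strains and re-runs the scan.  The discovery unit is a spot with at
    least one marker at or above the cutoff; candidate cutoffs are the
    sorted unique observed per-spot maxima.  When no cutoff satisfies the
    criterion (e.g. pure-null data) ``threshold`` is ``None``; an empty
    discovery grid raises ``RuntimeError``.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    if q <= 0:
        raise ValueError("q must be > 0")
    if log_m_correction not in ("none", "multiply", "divide"):
        raise ValueError("log_m_correction must be none|multiply|divide")
    rng = np.random.default_rng(seed)

    observed = scan(expression, genotypes)
    obs_max = observed.feature_max().to_numpy()
    grid = np.unique(obs_max)
    m = obs_max.size

    perm_counts = np.zeros((n_perm, grid.size))
    values = expression.values
    for p in range(n_perm):
        shuffled = ExpressionMatrix(
            features=expression.features.copy(),
            values=pd.DataFrame(
                rng.permuted(values.to_numpy(), axis=1),
                index=values.index,
                columns=values.columns,
            ),
        )
        perm_max = scan(shuffled, genotypes).feature_max().to_numpy()
        # discoveries at cutoff t: spots with max >= t
        perm_counts[p] = perm_max.size - np.searchsorted(np.sort(perm_max), grid, "left")
    fds = perm_counts.mean(axis=0)
    rds = (m - np.searchsorted(np.sort(obs_max), grid, "left")).astype(float)

    res = ThresholdResult(
        q=q,
        n_perm=n_perm,
        grid=grid,
        rds=rds,
        fds=fds,
        m=m,
        m0_ratio=m0_ratio,
        log_m_correction=log_m_correction,
        threshold=None,
    )
    if not (rds > 0).any():
        raise RuntimeError("no real discoveries at any cutoff")
    ok = np.flatnonzero((res.fdr <= q) & (rds > 0))
    res.threshold = float(grid[ok[0]]) if ok.size else None
    return res


def effect_size_for_r2(r2: float) -> float:
    """Allelic effect (noise-SD units) explaining ``r2`` at a balanced marker.

    Inverts ``R^2 = 0.25 a^2 / (0.25 a^2 + 1)`` under 0/1 genotype coding
    with unit noise: ``a = 2 sqrt(r2 / (1 - r2))``; r2 = 0.20 gives a = 1.
    """
    if not 0 <= r2 < 1:
        raise ValueError("r2 must be in [0, 1)")
    return 2.0 * np.sqrt(r2 / (1.0 - r2))


def analytic_power(
    n1: int, n0: int, r2: float, threshold: float = 3.2
) -> float:
    """Noncentral-F power of the single-marker test at -log10(p) > threshold.

    For group sizes ``n1``/``n0`` and an allelic effect sized for ``r2``
    at a balanced marker, the test statistic is noncentral
    F(1, n-2, ncp = a^2 n1 n0 / n).
    """
    n = n1 + n0
    a = effect_size_for_r2(r2)
    ncp = a * a * n1 * n0 / n
    crit = stats.f.isf(10.0**-threshold, 1, n - 2)
    return float(stats.ncf.sf(crit, 1, n - 2, ncp))


@dataclass
class PowerTable:
    """Per-r2 detection rate, effect-size error and location error."""

    table: pd.DataFrame  # r2, detection_rate, mean_abs_r2_error, mean_marker_error, mean_bp_error
    false_positive_rate: float
    threshold: float
    reps_per_marker: int


def simulate_power(
    genotypes: GenotypeMatrix,
    threshold: float = 3.2,
    r2_grid: np.ndarray | None = None,
    reps_per_marker: int = 10,
    ci_drop: float = 1.5,
    seed: int | None = None,
) -> PowerTable:
    """Map-aware power simulation of single-marker QTL.

    For every marker of the (pruned, informative) map and every explained-
    variance level, ``reps_per_marker`` phenotypes are simulated as
    ``effect_size_for_r2(r2) * genotype + N(0, 1)`` and scanned genome-
    wide.  A QTL counts as detected when the genome-wide peak exceeds
    ``threshold``, lies on the simulated marker's chromosome, and the
    simulated marker falls inside the peak's ``ci_drop`` confidence
    interval.  Phenotypes without a planted peak estimate the per-scan
    false-positive rate.
    """
    if genotypes.n_markers == 0:
        raise ValueError("empty genotype matrix")
    if r2_grid is None:
        r2_grid = np.arange(0.20, 0.801, 0.05)
    rng = np.random.default_rng(seed)

    G = genotypes.calls.to_numpy(dtype=float)  # strains x markers
    n_strains, n_markers = G.shape
    ind = np.nan_to_num(G, nan=0.5)
    markers = genotypes.markers
    chrom = markers["chrom"].to_numpy()
    pos = markers["pos_bp"].to_numpy()
    strain_index = genotypes.calls.index

    def scan_phenos(Y: np.ndarray) -> ScanMatrix:
        expr = ExpressionMatrix(
            features=pd.DataFrame(
                {
                    "spot_id": [f"sim{i}" for i in range(Y.shape[0])],
                    "gene_id": [f"sim{i}" for i in range(Y.shape[0])],
                    "chrom": None,
                    "pos_bp": np.nan,
                }
            ),
            values=pd.DataFrame(Y, index=[f"sim{i}" for i in range(Y.shape[0])], columns=strain_index),
        )
        return scan(expr, genotypes, min_strains=min(8, n_strains))

    rows = []
    for r2 in r2_grid:
        a = effect_size_for_r2(float(r2))
        # phenotype block: (marker, rep) x strains
        signal = np.repeat(ind.T, reps_per_marker, axis=0) * a
        noise = rng.normal(size=signal.shape)
        sm = scan_phenos(signal + noise)
        P = sm.neg_log10_p.to_numpy()
        true_marker = np.repeat(np.arange(n_markers), reps_per_marker)

        peak = P.argmax(axis=1)
        peak_val = P[np.arange(P.shape[0]), peak]
        above = peak_val > threshold
        same_chrom = chrom[peak] == chrom[true_marker]
        in_ci = np.zeros(P.shape[0], dtype=bool)
        for i in np.flatnonzero(above & same_chrom):
            cols = np.flatnonzero(chrom == chrom[peak[i]])
            lo, hi = _ci_bounds(P[i, cols], int(np.argmax(P[i, cols])), ci_drop)
            in_ci[i] = cols[lo] <= true_marker[i] <= cols[hi]
        detected = above & same_chrom & in_ci

        # winner's-curse-prone effect-size estimate at the detected peak
        df = np.count_nonzero(~np.isnan(G), axis=0) - 2
        est_r2 = np.full(P.shape[0], np.nan)
        for i in np.flatnonzero(detected):
            p10 = min(P[i, peak[i]], 300.0)
            f = stats.f.isf(10.0**-p10, 1, df[peak[i]])
            est_r2[i] = f / (f + df[peak[i]]) if np.isfinite(f) else 1.0
        r2_err = np.abs(est_r2[detected] - r2) if detected.any() else np.array([np.nan])
        marker_err = np.abs(peak - true_marker)[detected]
        bp_err = np.abs(pos[peak] - pos[true_marker])[detected]
        rows.append(
            (
                float(r2),
                float(detected.mean()),
                float(np.nanmean(r2_err)),
                float(marker_err.mean()) if detected.any() else np.nan,
                float(bp_err.mean()) if detected.any() else np.nan,
            )
        )

    # null phenotypes: family-wise false positives per scan
    null = rng.normal(size=(n_markers * reps_per_marker, n_strains))
    fp = float((scan_phenos(null).neg_log10_p.to_numpy().max(axis=1) > threshold).mean())

    table = pd.DataFrame(
        rows,
        columns=[
            "r2",
            "detection_rate",
            "mean_abs_r2_error",
            "mean_marker_error",
            "mean_bp_error",
        ],
    )
    return PowerTable(
        table=table,
        false_positive_rate=fp,
        threshold=threshold,
        reps_per_marker=reps_per_marker,
    )
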