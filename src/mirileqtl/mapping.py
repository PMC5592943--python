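"""Single-marker eQTL genome scan, peak calling and cis/trans classification.

Every spot's log2 intensity is regressed on the binary genotype at every
marker, ``y_ij ~ x_j + e_j``.  With a single binary regressor the OLS
F test is exactly the pooled-variance two-sample t test between the two
genotype groups, and the statistic is computed in that closed form,
vectorised over all spot x marker pairs.  Peaks per spot and chromosome
get a confidence interval from a 1.5 drop in -log10(p), and a spot is
classified cis when its gene lies within 2 Mb of the peak or inside the
confidence interval on the same chromosome.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .containers import ExpressionMatrix, GenotypeMatrix, P1

LOG10 = np.log(10.0)

#: Cap on -log10(p) so entries stay finite when a fit is exact.
NEGLOG10P_CAP = 350.0

EQTL_COLUMNS = [
    "spot_id",
    "gene_id",
    "gene_chrom",
    "gene_pos",
    "peak_chrom",
    "peak_pos",
    "neg_log10_p",
    "effect",
    "ci_start",
    "ci_end",
    "class",
]


@dataclass
class ScanMatrix:
    """Genome-scan result: spots x markers -log10(p) and signed effects."""

    neg_log10_p: pd.DataFrame  # spots x markers
    effect: pd.DataFrame  # mean(P1 group) - mean(P2 group), log2 units
    markers: pd.DataFrame  # marker_id, chrom, pos_bp
    skipped: pd.Series  # markers flagged monomorphic / underpowered

    def feature_max(self) -> pd.Series:
        return self.neg_log10_p.max(axis=1)


def neg_log10_p_from_t(t: np.ndarray, df: np.ndarray) -> np.ndarray:
    """Two-sided p of a t statistic as -log10(p), stable for huge |t|."""
    logp = np.log(2.0) + stats.t.logsf(np.abs(t), df)
    return np.minimum(-logp / LOG10, NEGLOG10P_CAP)


def scan(
    expression: ExpressionMatrix,
    genotypes: GenotypeMatrix,
    min_strains: int = 8,
    min_per_class: int = 2,
) -> ScanMatrix:
    """Scan every spot against every marker with the two-group linear model.

    Strains are intersected between the two inputs; missing genotype calls
    are excluded per marker.  Markers with fewer than ``min_per_class``
    strains in either genotype class are skipped (flagged, -log10(p) = 0).
    """
    shared = [s for s in expression.strains if s in set(genotypes.strains)]
    if len(shared) == 0:
        raise ValueError("expression and genotype strain sets do not overlap")
    if len(shared) < min_strains:
        raise ValueError(
            f"only {len(shared)} shared strains; need at least {min_strains}"
        )
    Y = expression.values[shared].to_numpy(dtype=float)  # spots x strains
    G = genotypes.calls.loc[shared].to_numpy(dtype=float)  # strains x markers

    A = (G == P1).astype(float)  # P1 indicator, 0 where missing
    V = (~np.isnan(G)).astype(float)
    n1 = A.sum(axis=0)
    nv = V.sum(axis=0)
    n0 = nv - n1
    usable = (n1 >= min_per_class) & (n0 >= min_per_class)
    if not usable.any():
        raise ValueError("no marker has two genotype classes with enough strains")

    with np.errstate(divide="ignore", invalid="ignore"):
        S1 = Y @ A
        Sv = Y @ V
        Q1 = (Y**2) @ A
        Qv = (Y**2) @ V
        m1 = S1 / n1
        m0 = (Sv - S1) / n0
        ssr = Qv - n1 * m1**2 - n0 * m0**2
        ssr = np.maximum(ssr, 0.0)  # guard tiny negative round-off
        df = nv - 2.0
        sp2 = ssr / df
        se = np.sqrt(sp2 * (1.0 / n1 + 1.0 / n0))
        t = (m1 - m0) / se

    # 0/0 (constant expression) -> no evidence; +-inf (exact fit) survives
    # into logsf and is capped by neg_log10_p_from_t.
    t = np.where(np.isnan(t), 0.0, t)
    neglogp = np.zeros_like(t)
    cols = np.flatnonzero(usable)
    neglogp[:, cols] = neg_log10_p_from_t(t[:, cols], df[cols])
    effect = np.where(usable, m1 - m0, np.nan)

    marker_ids = genotypes.markers["marker_id"]
    spot_ids = expression.features["spot_id"]
    return ScanMatrix(
        neg_log10_p=pd.DataFrame(neglogp, index=spot_ids, columns=marker_ids),
        effect=pd.DataFrame(effect, index=spot_ids, columns=marker_ids),
        markers=genotypes.markers.copy(),
        skipped=pd.Series(~usable, index=marker_ids, name="skipped"),
    )


def _ci_bounds(values: np.ndarray, peak: int, ci_drop: float) -> tuple[int, int]:
    """Contiguous run around ``peak`` with values > peak - ci_drop."""
    cut = values[peak] - ci_drop
    lo = peak
    while lo > 0 and values[lo - 1] > cut:
        lo -= 1
    hi = peak
    while hi < len(values) - 1 and values[hi + 1] > cut:
        hi += 1
    return lo, hi


def call_peaks(
    scanm: ScanMatrix,
    expression_features: pd.DataFrame,
    threshold: float,
    ci_drop: float = 1.5,
) -> pd.DataFrame:
    """Call one eQTL per spot per chromosome with any marker above threshold.

    The peak is the marker with maximal -log10(p) on that chromosome
    (leftmost on ties); the confidence interval is the maximal contiguous
    marker run around the peak whose -log10(p) exceeds peak - ``ci_drop``,
    reported in bp from its first to its last marker.  Returns an eQTL
    table (class column empty until :func:`classify_cis_trans`).
    """
    if threshold <= 0:
        raise ValueError("threshold must be > 0")
    markers = scanm.markers
    feat = expression_features.set_index("spot_id")
    chrom_index: dict[str, np.ndarray] = {
        str(c): sub.index.to_numpy() for c, sub in markers.groupby("chrom", sort=False)
    }
    P = scanm.neg_log10_p.to_numpy()
    E = scanm.effect.to_numpy()
    pos = markers["pos_bp"].to_numpy()

    rows = []
    for i, sid in enumerate(scanm.neg_log10_p.index):
        for chrom, cols in chrom_index.items():
            vals = P[i, cols]
            peak_local = int(np.argmax(vals))  # leftmost max
            if vals[peak_local] < threshold:
                continue
            lo, hi = _ci_bounds(vals, peak_local, ci_drop)
            j = cols[peak_local]
            g = feat.loc[sid]
            rows.append(
                (
                    sid,
                    g["gene_id"],
                    g["chrom"],
                    g["pos_bp"],
                    chrom,
                    int(pos[j]),
                    float(vals[peak_local]),
                    float(E[i, j]),
                    int(pos[cols[lo]]),
                    int(pos[cols[hi]]),
                    "",
                )
            )
    return pd.DataFrame(rows, columns=EQTL_COLUMNS)


def classify_cis_trans(
    records: pd.DataFrame, cis_window: int = 2_000_000
) -> pd.DataFrame:
    """Label each eQTL cis or trans.

    cis iff the gene lies on the peak chromosome AND (within ``cis_window``
    of the peak position OR inside the confidence interval); otherwise
    trans.  Unplaced genes (missing chromosome) are dropped with a warning
    count in the log.
    """
    rec = records.copy()
    placed = rec["gene_chrom"].notna() & rec["gene_pos"].notna()
    rec = rec[placed].reset_index(drop=True)
    same = rec["gene_chrom"].astype(str) == rec["peak_chrom"].astype(str)
    near = (rec["gene_pos"].astype(float) - rec["peak_pos"].astype(float)).abs() <= cis_window
    inside = (rec["gene_pos"].astype(float) >= rec["ci_start"].astype(float)) & (
        rec["gene_pos"].astype(float) <= rec["ci_end"].astype(float)
    )
    rec["class"] = np.where(same & (near | inside), "cis", "trans")
    return rec


def summarize_counts(records: pd.DataFrame) -> pd.DataFrame:
    """Gene- and spot-level eQTL counts by class and allelic-effect sign.

    Spots are deduplicated to genes; a gene represented by several spots
    can appear under both cis and trans, and under both signs.
    """
    rows = []
    for cls in ("cis", "trans"):
        sub = records[records["class"] == cls]
        for sign, name in ((1, "N2_higher"), (-1, "CB4856_higher")):
            ss = sub[np.sign(sub["effect"]) == sign]
            rows.append((cls, name, ss["gene_id"].nunique(), len(ss)))
        rows.append((cls, "total", sub["gene_id"].nunique(), len(sub)))
    return pd.DataFrame(rows, columns=["class", "sign", "n_genes", "n_spots"])
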