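"""Trans-band (eQTL hotspot) detection, replication and uniqueness tests.

Trans-eQTL spot peaks are counted per 1-Mb bin of the genome.  Under the
null that trans-eQTL scatter uniformly over the occupied bins, the count
per occupied bin is Poisson with mean lambda = total spots / occupied
bins; bins whose upper-tail probability falls below the significance
level are hotspot bins, and adjacent significant bins are merged into
trans-bands.  A band's specificity to the population is assessed with a
lower-tail Poisson test: given an expected replication rate (the
genome-wide fraction of trans-eQTL genes recovered in reference
experiments), fewer-than-expected replicated genes inside a band mark it
as unique to this population.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import gammaln, logsumexp


def poisson_tail(k: int, lam: float, side: str = "upper") -> float:
    """Exact cumulative Poisson tail, summed in log space.

    ``upper``: P(X >= k); ``lower``: P(X <= k).
    """
    if lam <= 0:
        raise ValueError("lam must be > 0")
    if k != int(k) or k < 0:
        raise ValueError("k must be a non-negative integer")
    k = int(k)

    def log_pmf(j: np.ndarray) -> np.ndarray:
        return -lam + j * np.log(lam) - gammaln(j + 1.0)

    if side == "lower":
        return float(np.exp(logsumexp(log_pmf(np.arange(0, k + 1)))))
    if side == "upper":
        if k == 0:
            return 1.0
        # sum the tail directly; terms beyond lam + 20 sqrt(lam) + 50 are
        # negligible relative to the included mass
        stop = int(max(k + 50, lam + 20.0 * np.sqrt(lam) + 50))
        return float(min(1.0, np.exp(logsumexp(log_pmf(np.arange(k, stop + 1))))))
    raise ValueError("side must be 'upper' or 'lower'")


def hotspot_count_cutoff(lam: float, alpha: float) -> int:
    """Smallest count c such that P(X > c) < alpha under Poisson(lam)."""
    c = 0
    while poisson_tail(c + 1, lam, side="upper") >= alpha:
        c += 1
    return c


@dataclass
class TransBand:
    """A merged run of adjacent significant 1-Mb bins."""

    chrom: str
    start_mb: float
    end_mb: float
    n_spots: int
    n_genes: int
    lam: float
    p_value: float
    member_bins: list[int]

    @property
    def label(self) -> str:
        return f"{self.chrom}: {self.start_mb:.1f}–{self.end_mb:.1f} Mb"


def bin_trans_counts(
    trans_records: pd.DataFrame, bin_size: int = 1_000_000
) -> pd.DataFrame:
    """Spot counts per half-open [start, start + bin_size) peak-position bin."""
    rec = trans_records
    bins = (rec["peak_pos"].astype(int) - 1) // bin_size  # 1-based coords
    tab = (
        rec.assign(bin=bins)
        .groupby(["peak_chrom", "bin"])
        .agg(n_spots=("spot_id", "size"), n_genes=("gene_id", "nunique"))
        .reset_index()
    )
    return tab.sort_values(["peak_chrom", "bin"], kind="stable").reset_index(drop=True)


def detect_trans_bands(
    trans_records: pd.DataFrame,
    bin_size: int = 1_000_000,
    sig_level: float = 0.001,
    merge: bool = True,
) -> tuple[list[TransBand], float]:
    """Detect trans-bands by the Poisson bin test.

    lambda = total trans spots / occupied bins; a bin is significant when
    its upper-tail probability P(X >= count) is below ``sig_level``;
    adjacent significant bins on a chromosome are merged (band p-value =
    min member-bin p).  Returns the bands and lambda.
    """
    if len(trans_records) == 0:
        return [], float("nan")
    counts = bin_trans_counts(trans_records, bin_size=bin_size)
    lam = float(counts["n_spots"].sum() / len(counts))
    counts["p"] = [
        poisson_tail(int(k), lam, side="upper") for k in counts["n_spots"]
    ]
    sig = counts[counts["p"] < sig_level]

    mb = bin_size / 1_000_000
    bands: list[TransBand] = []
    for chrom, sub in sig.groupby("peak_chrom", sort=False):
        sub = sub.sort_values("bin")
        runs: list[list[int]] = []
        for b in sub["bin"]:
            if merge and runs and b == runs[-1][-1] + 1:
                runs[-1].append(int(b))
            else:
                runs.append([int(b)])
        for run in runs:
            members = counts[
                (counts["peak_chrom"] == chrom) & (counts["bin"].isin(run))
            ]
            in_band = trans_records[
                (trans_records["peak_chrom"] == chrom)
                & ((trans_records["peak_pos"].astype(int) - 1) // bin_size).isin(run)
            ]
            bands.append(
                TransBand(
                    chrom=str(chrom),
                    start_mb=run[0] * mb,
                    end_mb=(run[-1] + 1) * mb,
                    n_spots=int(members["n_spots"].sum()),
                    n_genes=int(in_band["gene_id"].nunique()),
                    lam=lam,
                    p_value=float(members["p"].min()),
                    member_bins=run,
                )
            )
    bands.sort(key=lambda b: (b.chrom, b.start_mb))
    return bands, lam


@dataclass
class ReplicationReport:
    """Gene-level replication of eQTL against reference experiments."""

    per_gene: pd.DataFrame  # gene_id, class, peak_chrom, replicated
    cis_rate: float
    trans_rate: float

    @property
    def trans_counts(self) -> tuple[int, int]:
        t = self.per_gene[self.per_gene["class"] == "trans"]
        return int(t["replicated"].sum()), len(t)


REFERENCE_COLUMNS = {"gene_id", "class", "peak_chrom"}


def replication_overlap(
    records: pd.DataFrame, reference_sets: list[pd.DataFrame]
) -> ReplicationReport:
    """Check each eQTL gene against reference experiment eQTL tables.

    A cis gene replicates when any reference set contains a cis-eQTL for
    the same gene; a trans gene replicates when any reference set contains
    a trans-eQTL for the same gene on the same chromosome.
    """
    for i, ref in enumerate(reference_sets):
        missing = REFERENCE_COLUMNS - set(ref.columns)
        if missing:
            raise ValueError(
                f"reference set {i} missing required columns {sorted(missing)}"
            )
    cis_ref: set[str] = set()
    trans_ref: set[tuple[str, str]] = set()
    for ref in reference_sets:
        cis_ref |= set(ref.loc[ref["class"] == "cis", "gene_id"])
        t = ref[ref["class"] == "trans"]
        trans_ref |= set(zip(t["gene_id"].astype(str), t["peak_chrom"].astype(str)))

    rows = []
    for cls in ("cis", "trans"):
        sub = records[records["class"] == cls]
        for gid, gsub in sub.groupby("gene_id", sort=False):
            if cls == "cis":
                rep = str(gid) in cis_ref
            else:
                rep = any(
                    (str(gid), str(c)) in trans_ref for c in gsub["peak_chrom"]
                )
            rows.append((gid, cls, gsub["peak_chrom"].iloc[0], bool(rep)))
    per_gene = pd.DataFrame(rows, columns=["gene_id", "class", "peak_chrom", "replicated"])

    def rate(cls: str) -> float:
        sub = per_gene[per_gene["class"] == cls]
        return float(sub["replicated"].mean()) if len(sub) else float("nan")

    return ReplicationReport(per_gene=per_gene, cis_rate=rate("cis"), trans_rate=rate("trans"))


def transband_uniqueness_test(
    n_genes: int, n_replicated: int, expected_rate: float
) -> float:
    """Lower-tail Poisson test for depletion of replicated genes in a band.

    With lambda = expected_rate * n_genes, returns P(X <= n_replicated):
    a small value means far fewer band genes replicate in reference
    experiments than the genome-wide rate predicts — the band is specific
    to this population.
    """
    if not 0 <= n_replicated <= n_genes:
        raise ValueError("need 0 <= n_replicated <= n_genes")
    if not 0 < expected_rate < 1:
        raise ValueError("expected_rate must be in (0, 1)")
    return poisson_tail(n_replicated, expected_rate * n_genes, side="lower")


def band_uniqueness_table(
    bands: list[TransBand],
    records: pd.DataFrame,
    report: ReplicationReport,
    expected_rate: float | None = None,
) -> pd.DataFrame:
    """Per-band replication counts and uniqueness p-values.

    ``expected_rate`` defaults to the genome-wide trans replication rate
    from ``report``.
    """
    if expected_rate is None:
        n_rep, n_tot = report.trans_counts
        if n_tot == 0 or n_rep == 0:
            raise ValueError("cannot derive expected replication rate (no trans genes)")
        expected_rate = n_rep / n_tot
    rep_genes = set(
        report.per_gene.loc[
            (report.per_gene["class"] == "trans") & report.per_gene["replicated"],
            "gene_id",
        ]
    )
    rows = []
    for band in bands:
        lo, hi = band.start_mb * 1e6, band.end_mb * 1e6
        in_band = records[
            (records["class"] == "trans")
            & (records["peak_chrom"].astype(str) == band.chrom)
            & (records["peak_pos"].astype(float) > lo)
            & (records["peak_pos"].astype(float) <= hi)
        ]
        genes = set(in_band["gene_id"])
        n_rep = len(genes & rep_genes)
        p = transband_uniqueness_test(len(genes), n_rep, expected_rate)
        rows.append(
            (band.label, len(genes), len(in_band), n_rep, expected_rate, p)
        )
    return pd.DataFrame(
        rows,
        columns=["band", "n_genes", "n_spots", "n_replicated", "expected_rate", "p_uniqueness"],
    )
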