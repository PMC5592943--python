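"""Genetic-map expansion from expression data.

A strain's genotype along the genome can be read off its transcriptome:
after centering each spot on the mean of the two parental profiles, the
centred intensities of genes with strong cis effects co-vary with the
local genotype.  Correlating the centred profile of 20 consecutive
reference cis-eQTL against their known signed effects yields one
"expression marker" per window — positive correlation means the window's
genotype stems from the N2-like parent (P1), negative from the
CB4856-like parent (P2).  Weakly correlated windows stay missing and are
imputed from flanking markers; chromosome ends are extended from the
distal-most assigned marker; finally, markers that are uninformative in
the population (minor-genotype frequency too low) or that duplicate an
adjacent marker's strain pattern are pruned.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .containers import ExpressionMatrix, GenotypeMatrix, ReferenceCisPanel, P1, P2

logger = logging.getLogger(__name__)

CALL_COLUMNS = ["strain", "window_id", "chrom", "pos_bp", "r", "call", "provenance"]


def center_on_parents(expression: ExpressionMatrix) -> ExpressionMatrix:
    """Subtract the mean of the two parental profiles from every strain.

    ``R(x, i) = Y(x, i) - 0.5 * (Y_P1(i) + Y_P2(i))`` with parental means
    taken over their replicate columns.  Parental columns are centred the
    same way and retained for QC.
    """
    parents = expression.parent_means()
    mid = 0.5 * (parents["P1"] + parents["P2"])
    values = expression.values.sub(mid, axis=0)
    parental = expression.parental_values.sub(mid, axis=0)
    return ExpressionMatrix(
        features=expression.features.copy(),
        values=values,
        parental_values=parental,
        parental_genotype=dict(expression.parental_genotype),
    )


def _window_correlations(block: np.ndarray, ref: np.ndarray) -> np.ndarray:
    """Pearson r of every column of ``block`` (genes x strains) against ``ref``."""
    ec = ref - ref.mean()
    e_norm = np.linalg.norm(ec)
    bc = block - block.mean(axis=0)
    b_norm = np.linalg.norm(bc, axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        r = (ec @ bc) / (e_norm * b_norm)
    r[~np.isfinite(r)] = np.nan  # zero-variance column or reference
    return r


def call_expression_markers(
    centered: ExpressionMatrix,
    panel: ReferenceCisPanel,
    window: int = 20,
    call_threshold: float = 0.6,
    include_parents: bool = True,
) -> pd.DataFrame:
    """Call expression markers by windowed correlation against a cis panel.

    Panel genes present in ``centered`` (matched by gene id) are ordered by
    genomic position and partitioned into consecutive non-overlapping
    blocks of ``window`` genes: ``floor(n_matched / window)`` markers.  For
    every strain and block the Pearson correlation between the block's
    reference effects and the strain's centred intensities is computed;
    ``r > call_threshold`` calls P1, ``r < -call_threshold`` calls P2,
    otherwise the marker is missing for that strain.  The representative
    position of a block is its median gene.

    Returns a long-format table with columns
    ``strain, window_id, chrom, pos_bp, r, call, provenance``; parental
    replicate columns are included as extra strains when
    ``include_parents`` (used by :func:`qc_filter_markers`).
    """
    if window < 2:
        raise ValueError("window must be >= 2")
    feat = centered.features.set_index("spot_id")
    gene_to_spot: dict[str, str] = {}
    for sid, gid in feat["gene_id"].items():
        gene_to_spot.setdefault(gid, sid)  # first spot represents the gene

    matched = panel.table[panel.table["gene_id"].isin(gene_to_spot)].reset_index(drop=True)
    n_markers = len(matched) // window
    if n_markers < 1:
        raise ValueError(
            f"only {len(matched)} panel genes matched; need at least one window of {window}"
        )

    spots = [gene_to_spot[g] for g in matched["gene_id"]]
    values = centered.values.loc[spots]  # genes x strains, panel order
    columns = list(values.columns)
    mat = values.to_numpy()
    if include_parents and centered.parental_values is not None:
        pv = centered.parental_values.loc[spots]
        mat = np.hstack([mat, pv.to_numpy()])
        columns = columns + list(pv.columns)
    effects = matched["effect"].to_numpy()

    rows = []
    for w in range(n_markers):
        lo, hi = w * window, (w + 1) * window
        block = matched.iloc[lo:hi]
        med = block.iloc[len(block) // 2]
        chrom, pos = str(med["chrom"]), int(med["pos_bp"])
        ref = effects[lo:hi]
        if np.std(ref) == 0:
            logger.warning("window %d has zero reference-effect variance", w)
        r = _window_correlations(mat[lo:hi], ref)
        call = np.where(r > call_threshold, P1, np.where(r < -call_threshold, P2, np.nan))
        for s, strain in enumerate(columns):
            rows.append((strain, w, chrom, pos, r[s], call[s], "correlated"))
    return pd.DataFrame(rows, columns=CALL_COLUMNS)


def qc_filter_markers(
    calls: pd.DataFrame,
    parental_genotype: dict[str, str],
    min_fraction_called: float = 0.5,
    qc_threshold: float = 0.5,
) -> pd.DataFrame:
    """Drop windows that misgenotype a parental replicate or correlate weakly.

    A window is kept only if (a) every parental replicate column is called
    as its own genotype and (b) the fraction of sample strains with
    ``|r| > qc_threshold`` exceeds ``min_fraction_called``.  Parental rows
    are removed from the output.
    """
    expected = {"P1": P1, "P2": P2}
    is_parent = calls["strain"].isin(parental_genotype)
    samples = calls[~is_parent]
    parents = calls[is_parent]

    keep = []
    for w, pw in parents.groupby("window_id"):
        ok = all(
            row["call"] == expected[parental_genotype[row["strain"]]]
            for _, row in pw.iterrows()
        )
        if not ok:
            continue
        sw = samples[samples["window_id"] == w]
        frac = float((sw["r"].abs() > qc_threshold).mean())
        if frac > min_fraction_called:
            keep.append(w)
    if not keep:
        logger.warning("qc_filter_markers: no windows passed QC")
    return samples[samples["window_id"].isin(keep)].reset_index(drop=True)


def impute_and_extend(
    calls: pd.DataFrame,
) -> tuple[GenotypeMatrix, pd.DataFrame]:
    """Build a genotype matrix from marker calls, imputing missing windows.

    Per strain and chromosome (markers in positional order): a missing call
    flanked by two identical calls becomes that call (provenance
    ``imputed``); flanked by discordant calls it stays missing — the
    interval contains a crossover (provenance ``crossover``); missing
    calls distal to the outermost assigned marker copy it (provenance
    ``end-extended``).  Returns the matrix and a same-shape provenance
    table.
    """
    marker_tab = (
        calls[["window_id", "chrom", "pos_bp"]]
        .drop_duplicates()
        .sort_values(["chrom", "pos_bp", "window_id"], kind="stable")
        .reset_index(drop=True)
    )
    marker_tab["marker_id"] = [
        f"EM{int(w):04d}" for w in marker_tab["window_id"]
    ]
    order = marker_tab["window_id"].to_list()
    strains = sorted(calls["strain"].unique())

    wide = calls.pivot(index="strain", columns="window_id", values="call")
    wide = wide.reindex(index=strains, columns=order)

    chrom_of = dict(zip(marker_tab["window_id"], marker_tab["chrom"]))
    out = wide.astype(float).copy()
    prov = pd.DataFrame("correlated", index=wide.index, columns=wide.columns)
    for strain in strains:
        for chrom in marker_tab["chrom"].unique():
            wins = [w for w in order if chrom_of[w] == chrom]
            vec = wide.loc[strain, wins].to_numpy(dtype=float)
            assigned = np.flatnonzero(~np.isnan(vec))
            if assigned.size == 0:
                raise ValueError(
                    f"strain {strain!r} has no called marker on chromosome {chrom}"
                )
            filled = vec.copy()
            tag = np.array(["correlated"] * len(vec), dtype=object)
            tag[np.isnan(vec)] = "crossover"
            # interior: fill gaps whose two flanking assigned calls agree
            for lo, hi in zip(assigned[:-1], assigned[1:]):
                if hi - lo > 1 and vec[lo] == vec[hi]:
                    filled[lo + 1 : hi] = vec[lo]
                    tag[lo + 1 : hi] = "imputed"
            # ends: copy the distal-most assigned call outward
            filled[: assigned[0]] = vec[assigned[0]]
            tag[: assigned[0]] = "end-extended"
            filled[assigned[-1] + 1 :] = vec[assigned[-1]]
            tag[assigned[-1] + 1 :] = "end-extended"
            out.loc[strain, wins] = filled
            prov.loc[strain, wins] = tag

    markers = marker_tab[["marker_id", "chrom", "pos_bp"]].reset_index(drop=True)
    geno = pd.DataFrame(
        out.to_numpy(dtype=float), index=strains, columns=markers["marker_id"]
    )
    provenance = pd.DataFrame(
        prov.to_numpy(), index=strains, columns=markers["marker_id"]
    )
    return GenotypeMatrix(calls=geno, markers=markers), provenance


def minor_genotype_frequency(genotypes: GenotypeMatrix) -> pd.Series:
    """Per-marker frequency of the rarer parental genotype (missing excluded)."""
    calls = genotypes.calls
    p1 = (calls == P1).sum(axis=0)
    p2 = (calls == P2).sum(axis=0)
    total = (p1 + p2).replace(0, np.nan)
    freq = pd.concat([p1 / total, p2 / total], axis=1).min(axis=1)
    return freq.fillna(0.0)


def prune_informative_markers(
    genotypes: GenotypeMatrix, min_minor_freq: float = 0.15
) -> tuple[GenotypeMatrix, pd.DataFrame]:
    """Keep informative crossover-border markers.

    Drops markers whose minor-genotype frequency is ``<= min_minor_freq``;
    within every run of adjacent markers whose genotype columns are
    identical across all strains (same chromosome), keeps only the first —
    the representative of the crossover border.  Also returns the
    marker-marker correlation matrix of the pruned map for QC.
    """
    freq = minor_genotype_frequency(genotypes)
    keep_mask = (freq > min_minor_freq).to_numpy()
    if not keep_mask.any():
        raise ValueError("all markers pruned: no informative markers remain")
    idx = np.flatnonzero(keep_mask)
    g = genotypes.subset_markers(idx)

    # crossover-border dedup on the already-filtered map
    cols = g.calls.to_numpy(dtype=float)
    chroms = g.markers["chrom"].to_numpy()
    keep2 = [0]
    for j in range(1, cols.shape[1]):
        same_chrom = chroms[j] == chroms[keep2[-1]]
        a, b = cols[:, j], cols[:, keep2[-1]]
        identical = np.array_equal(np.nan_to_num(a, nan=-1), np.nan_to_num(b, nan=-1))
        if same_chrom and identical:
            continue
        keep2.append(j)
    pruned = g.subset_markers(np.array(keep2))

    filled = np.nan_to_num(pruned.calls.to_numpy(dtype=float), nan=0.5)
    corr = pd.DataFrame(
        np.corrcoef(filled, rowvar=False),
        index=pruned.markers["marker_id"],
        columns=pruned.markers["marker_id"],
    )
    return pruned, corr
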