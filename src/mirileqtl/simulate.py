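"""Synthetic miRIL populations with a known eQTL architecture.

The generator emulates the design of a mutation-introgressed RIL (miRIL)
panel: two homozygous parents (P1 = N2-like, P2 = CB4856-like) are crossed,
the F1 is selfed, and F2 individuals carrying the introgressed mutation
homozygously are selfed for several generations.  Selection at the mutant
locus keeps that allele fixed for P1 and skews allele frequencies at linked
markers toward P1, decaying with genetic distance; unlinked markers
segregate 1:1 in expectation.

Expression data are simulated on top of the genotypes as
``baseline + sum(effect_k * [genotype at target marker k == P1]) + N(0, sd)``
with planted cis effects (biased toward higher expression on the N2 allele),
scattered trans effects, and clustered trans-bands, so every downstream
stage can be checked against the planted truth.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .containers import (
    ExpressionMatrix,
    GenotypeMatrix,
    ReferenceCisPanel,
    TrueArchitecture,
)

#: Chromosome lengths (bp) approximating the six C. elegans chromosomes.
DEFAULT_CHROMOSOMES: list[tuple[str, int]] = [
    ("I", 15_000_000),
    ("II", 15_000_000),
    ("III", 13_000_000),
    ("IV", 17_000_000),
    ("V", 21_000_000),
    ("X", 17_000_000),
]

#: Selected introgressed locus: the Ras pathway mutation on chromosome IV.
DEFAULT_SELECTED_LOCUS: tuple[str, int] = ("IV", 11_700_000)

#: ~247 markers over ~98 Mb -> one marker per ~400 kb.
DEFAULT_MARKER_SPACING = 400_000

#: Fraction of planted cis effects that are positive (higher in N2),
#: matching the observed N2 bias of cis-eQTL.
CIS_POSITIVE_FRACTION = 0.71


def _marker_positions(length_bp: int, spacing_bp: int) -> np.ndarray:
    start = spacing_bp // 2 + 1
    return np.arange(start, length_bp + 1, spacing_bp, dtype=np.int64)


def _gamete(
    rng: np.random.Generator,
    hap0: np.ndarray,
    hap1: np.ndarray,
    marker_pos: np.ndarray,
    length_bp: int,
    recomb_rate: float,
) -> np.ndarray:
    """One meiotic product: crossovers Poisson(recomb_rate), uniform in bp."""
    n_xo = rng.poisson(recomb_rate)
    start = rng.integers(0, 2)
    if n_xo == 0:
        return hap0 if start == 0 else hap1
    xo = np.sort(rng.uniform(1, length_bp, size=n_xo))
    which = (start + np.searchsorted(xo, marker_pos)) % 2
    return np.where(which == 0, hap0, hap1)


def simulate_miril_genotypes(
    n_lines: int = 33,
    chromosomes: list[tuple[str, int]] | None = None,
    marker_spacing: int = DEFAULT_MARKER_SPACING,
    selected_locus: tuple[str, int] | None = DEFAULT_SELECTED_LOCUS,
    recomb_rate: float = 1.0,
    n_selfing: int = 10,
    seed: int | None = None,
) -> GenotypeMatrix:
    """Simulate a homozygous miRIL genotype matrix.

    Each line descends from one F2 individual of a P1 x P2 cross, selected
    to be homozygous P1 at ``selected_locus``, then selfed ``n_selfing``
    generations.  Residual heterozygosity after selfing is forced to a
    random parental allele.  ``recomb_rate`` is the expected number of
    crossovers per chromosome per meiosis.
    """
    if n_lines < 2:
        raise ValueError("n_lines must be >= 2")
    chroms = list(chromosomes) if chromosomes is not None else list(DEFAULT_CHROMOSOMES)
    rng = np.random.default_rng(seed)

    marker_rows = []
    pos_by_chrom: dict[str, np.ndarray] = {}
    for name, length in chroms:
        pos = _marker_positions(length, marker_spacing)
        if pos.size == 0:
            raise ValueError(f"zero markers on chromosome {name}")
        pos_by_chrom[name] = pos
        for p in pos:
            marker_rows.append((f"{name}:{int(p)}", name, int(p)))
    markers = pd.DataFrame(marker_rows, columns=["marker_id", "chrom", "pos_bp"])

    sel_chrom_idx = None
    sel_marker_idx = None
    if selected_locus is not None:
        sel_chrom, sel_pos = selected_locus
        if sel_chrom not in pos_by_chrom:
            raise ValueError(f"selected locus chromosome {sel_chrom!r} not declared")
        length = dict(chroms)[sel_chrom]
        if not (1 <= sel_pos <= length):
            raise ValueError("selected locus outside chromosome bounds")
        sel_chrom_idx = [c for c, _ in chroms].index(sel_chrom)
        sel_marker_idx = int(np.abs(pos_by_chrom[sel_chrom] - sel_pos).argmin())

    lengths = [length for _, length in chroms]
    lines = np.empty((n_lines, len(markers)), dtype=float)
    for li in range(n_lines):
        # F1: fully heterozygous; pairs of haplotypes per chromosome.
        genome = []
        for name, length in chroms:
            n = pos_by_chrom[name].size
            genome.append((np.ones(n), np.zeros(n)))

        # F2 with selection for P1 homozygosity at the introgressed locus.
        while True:
            f2 = []
            for ci, (name, length) in enumerate(chroms):
                pos = pos_by_chrom[name]
                g1 = _gamete(rng, *genome[ci], pos, length, recomb_rate)
                g2 = _gamete(rng, *genome[ci], pos, length, recomb_rate)
                f2.append((g1, g2))
            if sel_chrom_idx is None:
                break
            a, b = f2[sel_chrom_idx]
            if a[sel_marker_idx] == 1.0 and b[sel_marker_idx] == 1.0:
                break
        genome = f2

        for _ in range(n_selfing):
            genome = [
                (
                    _gamete(rng, *genome[ci], pos_by_chrom[name], lengths[ci], recomb_rate),
                    _gamete(rng, *genome[ci], pos_by_chrom[name], lengths[ci], recomb_rate),
                )
                for ci, (name, _) in enumerate(chroms)
            ]

        # Force residual heterozygosity to a random parental allele.
        row = []
        for a, b in genome:
            het = a != b
            g = a.copy()
            g[het] = rng.integers(0, 2, size=het.sum()).astype(float)
            row.append(g)
        lines[li] = np.concatenate(row)

    calls = pd.DataFrame(
        lines,
        index=[f"miRIL{i + 1:03d}" for i in range(n_lines)],
        columns=markers["marker_id"],
    )
    return GenotypeMatrix(calls=calls, markers=markers, selected_locus=selected_locus)


def simulate_reference_cis_panel(
    genotypes: GenotypeMatrix,
    n_genes: int = 8480,
    effect_scale: float = 2.5,
    seed: int | None = None,
) -> ReferenceCisPanel:
    """Reference cis-eQTL effect panel emulating a strong, pre-selected set.

    Genes are placed uniformly along the chromosomes of ``genotypes``.
    Effect magnitudes are Uniform(effect_scale, 2*effect_scale) — a
    genotyping panel is built from the strongest cis effects of a prior
    experiment — with random sign (positive = higher in P1/N2); both signs
    are always represented.  The default size (8480 genes, i.e. 424
    windows of 20) matches the density at which windowed genotype calling
    localises crossovers well below the window span.
    """
    if n_genes < 1:
        raise ValueError("n_genes must be >= 1")
    if effect_scale <= 0:
        raise ValueError("effect_scale must be > 0 (panel effects are nonzero)")
    rng = np.random.default_rng(seed)
    chrom_len = (
        genotypes.markers.groupby("chrom", sort=False)["pos_bp"].max().astype(float)
    )
    chroms = chrom_len.index.to_numpy()
    weights = chrom_len.to_numpy() / chrom_len.sum()
    gchrom = rng.choice(chroms, size=n_genes, p=weights)
    gpos = np.array(
        [rng.integers(1, int(chrom_len[c]) + 1) for c in gchrom], dtype=np.int64
    )
    mag = rng.uniform(effect_scale, 2 * effect_scale, size=n_genes)
    sign = rng.choice([-1.0, 1.0], size=n_genes)
    if n_genes >= 2 and np.all(sign == sign[0]):
        sign[0] = -sign[0]
    table = pd.DataFrame(
        {
            "gene_id": [f"ref{i + 1:05d}" for i in range(n_genes)],
            "chrom": gchrom,
            "pos_bp": gpos,
            "effect": mag * sign,
        }
    )
    return ReferenceCisPanel(table=table)


def plant_architecture(
    genotypes: GenotypeMatrix,
    n_features: int = 5000,
    panel: ReferenceCisPanel | None = None,
    cis_fraction: float = 0.08,
    trans_fraction: float = 0.04,
    n_bands: int = 2,
    band_size: int = 60,
    effect_low: float = 0.5,
    effect_high: float = 3.0,
    noise_sd: float = 1.0,
    baseline: float = 8.0,
    seed: int | None = None,
) -> TrueArchitecture:
    """Plant a known eQTL architecture over a genotype matrix.

    The feature set consists of (in order): one spot per panel gene with a
    cis effect equal to the panel effect (so expression-marker genotyping
    has its probes), ``cis_fraction`` of features with a cis effect at the
    marker nearest their own position (sign positive with probability
    0.71, the N2 bias), ``trans_fraction`` scattered trans effects,
    ``n_bands`` trans-bands of ``band_size`` spots all targeting one
    randomly chosen marker, and unregulated noise-only features.
    Effect magnitudes are Uniform(effect_low, effect_high) in noise-SD units.
    """
    rng = np.random.default_rng(seed)
    markers = genotypes.markers
    chrom_len = markers.groupby("chrom", sort=False)["pos_bp"].max()
    chroms = chrom_len.index.to_numpy()
    weights = chrom_len.to_numpy(dtype=float) / float(chrom_len.sum())

    feat_rows: list[tuple[str, str, str, int]] = []
    eff_rows: list[tuple[str, str, float, str, str]] = []

    def random_position() -> tuple[str, int]:
        c = rng.choice(chroms, p=weights)
        return str(c), int(rng.integers(1, int(chrom_len[c]) + 1))

    spot_n = 0

    def new_spot(gene_id: str, chrom: str, pos: int) -> str:
        nonlocal spot_n
        spot_n += 1
        sid = f"spot{spot_n:06d}"
        feat_rows.append((sid, gene_id, chrom, pos))
        return sid

    if panel is not None:
        for _, g in panel.table.iterrows():
            sid = new_spot(str(g["gene_id"]), str(g["chrom"]), int(g["pos_bp"]))
            mi = genotypes.nearest_marker(str(g["chrom"]), int(g["pos_bp"]))
            eff_rows.append(
                (sid, markers.at[mi, "marker_id"], float(g["effect"]), "cis", "")
            )

    n_cis = int(round(cis_fraction * n_features))
    n_trans = int(round(trans_fraction * n_features))
    n_band_feats = n_bands * band_size
    n_null = n_features - n_cis - n_trans - n_band_feats
    if n_null < 0:
        raise ValueError("architecture fractions exceed n_features")

    gene_n = 0

    def new_gene() -> str:
        nonlocal gene_n
        gene_n += 1
        return f"gene{gene_n:06d}"

    for _ in range(n_cis):
        chrom, pos = random_position()
        sid = new_spot(new_gene(), chrom, pos)
        mi = genotypes.nearest_marker(chrom, pos)
        mag = rng.uniform(effect_low, effect_high)
        sign = 1.0 if rng.random() < CIS_POSITIVE_FRACTION else -1.0
        eff_rows.append((sid, markers.at[mi, "marker_id"], mag * sign, "cis", ""))

    for _ in range(n_trans):
        chrom, pos = random_position()
        sid = new_spot(new_gene(), chrom, pos)
        # target on a different chromosome -> unambiguously trans
        other = markers[markers["chrom"] != chrom]
        mi = int(other.index[rng.integers(0, len(other))])
        mag = rng.uniform(effect_low, effect_high)
        sign = rng.choice([-1.0, 1.0])
        eff_rows.append((sid, markers.at[mi, "marker_id"], mag * sign, "trans", ""))

    for b in range(n_bands):
        mi = int(rng.integers(0, len(markers)))
        band_chrom = markers.at[mi, "chrom"]
        band_id = f"band{b + 1}"
        for _ in range(band_size):
            while True:
                chrom, pos = random_position()
                if chrom != band_chrom:
                    break
            sid = new_spot(new_gene(), chrom, pos)
            mag = rng.uniform(max(effect_low, 1.5), effect_high)
            sign = rng.choice([-1.0, 1.0])
            eff_rows.append(
                (sid, markers.at[mi, "marker_id"], mag * sign, "transband", band_id)
            )

    for _ in range(n_null):
        chrom, pos = random_position()
        new_spot(new_gene(), chrom, pos)

    features = pd.DataFrame(feat_rows, columns=["spot_id", "gene_id", "chrom", "pos_bp"])
    effects = pd.DataFrame(
        eff_rows, columns=["spot_id", "marker_id", "effect", "kind", "band_id"]
    )
    return TrueArchitecture(
        features=features, effects=effects, noise_sd=noise_sd, baseline=baseline
    )


def truth_genotype_at(
    genotypes: GenotypeMatrix, chrom: str, pos_bp: int
) -> pd.Series:
    """True genotype of every strain at an arbitrary genomic position.

    The call is read from the two markers flanking ``pos_bp``; when they
    disagree the position sits inside a crossover interval and the truth
    is undefined (NaN).  Used to evaluate expression-marker genotyping
    against simulated truth without penalising breakpoint ambiguity.
    """
    sub = genotypes.markers[genotypes.markers["chrom"] == chrom]
    if sub.empty:
        raise ValueError(f"no markers on chromosome {chrom!r}")
    pos = sub["pos_bp"].to_numpy()
    right = int(np.searchsorted(pos, pos_bp))
    if right < len(pos) and pos[right] == pos_bp:
        return genotypes.calls[sub.iloc[right]["marker_id"]].copy()
    left = max(right - 1, 0)
    right = min(right, len(pos) - 1)
    a = genotypes.calls[sub.iloc[left]["marker_id"]]
    b = genotypes.calls[sub.iloc[right]["marker_id"]]
    return a.where(a == b)


def simulate_expression(
    genotypes: GenotypeMatrix,
    architecture: TrueArchitecture,
    n_parental_replicates: int = 4,
    seed: int | None = None,
) -> ExpressionMatrix:
    """Simulate log2 expression from genotypes and a planted architecture.

    ``value(feature, strain) = baseline + sum(effect * [call == P1]) + N(0, sd)``.
    Parental replicate columns are generated from pure-P1 and pure-P2
    genotype rows with the same noise model.  Deterministic given ``seed``.
    """
    unknown = set(architecture.effects["marker_id"]) - set(genotypes.calls.columns)
    if unknown:
        raise ValueError(f"effects reference unknown markers: {sorted(unknown)[:3]}")
    rng = np.random.default_rng(seed)

    features = architecture.features
    spot_ids = features["spot_id"].to_list()
    spot_idx = {s: i for i, s in enumerate(spot_ids)}
    marker_idx = {m: j for j, m in enumerate(genotypes.calls.columns)}

    n_feat, n_markers = len(spot_ids), len(marker_idx)
    E = np.zeros((n_feat, n_markers))
    for _, row in architecture.effects.iterrows():
        E[spot_idx[row["spot_id"]], marker_idx[row["marker_id"]]] += row["effect"]

    G = genotypes.calls.to_numpy(dtype=float)  # strains x markers
    ind = np.nan_to_num(G, nan=0.5)  # missing calls contribute the mean
    signal = E @ ind.T  # features x strains
    values = (
        architecture.baseline
        + signal
        + rng.normal(0.0, architecture.noise_sd, size=signal.shape)
    )
    values_df = pd.DataFrame(values, index=spot_ids, columns=genotypes.strains)

    par_cols, par_geno = [], {}
    profiles = {"P1": E.sum(axis=1), "P2": np.zeros(n_feat)}
    par_data = {}
    for geno in ("P1", "P2"):
        for r in range(n_parental_replicates):
            col = f"{geno}_rep{r + 1}"
            par_data[col] = (
                architecture.baseline
                + profiles[geno]
                + rng.normal(0.0, architecture.noise_sd, size=n_feat)
            )
            par_cols.append(col)
            par_geno[col] = geno
    parental = pd.DataFrame(par_data, index=spot_ids)

    return ExpressionMatrix(
        features=features.copy(),
        values=values_df,
        parental_values=parental,
        parental_genotype=par_geno,
    )
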