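"""Core in-memory containers for the miRIL eQTL pipeline.

Conventions used throughout the package:

* Genotypes are biallelic and homozygous.  The N2-like parental allele
  (``P1``) is coded ``1.0``, the CB4856-like allele (``P2``) is coded
  ``0.0`` and missing calls are ``NaN``.  With this coding an allelic
  effect in noise-SD units of ``a`` at a balanced marker explains
  ``0.25 a^2 / (0.25 a^2 + 1)`` of the phenotypic variance.
* Genomic coordinates are 1-based inclusive base pairs.
* Expression values are on the log2 intensity scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

P1 = 1.0
P2 = 0.0


def _check_positions_increasing(markers: pd.DataFrame) -> None:
    for chrom, sub in markers.groupby("chrom", sort=False):
        pos = sub["pos_bp"].to_numpy()
        if np.any(np.diff(pos) <= 0):
            raise ValueError(f"marker positions not strictly increasing on {chrom}")


@dataclass
class GenotypeMatrix:
    """Homozygous strain-by-marker genotype calls with a genomic marker map.

    Parameters
    ----------
    calls
        DataFrame indexed by strain, one column per marker id, values in
        {1.0 (P1/N2), 0.0 (P2/CB4856), NaN (missing)}.
    markers
        Marker map with columns ``marker_id``, ``chrom``, ``pos_bp`` in the
        same order as the columns of ``calls``.
    selected_locus
        Optional ``(chrom, pos_bp)`` of a locus driven to homozygosity for
        the P1 allele in every line (the introgressed mutation).
    """

    calls: pd.DataFrame
    markers: pd.DataFrame
    selected_locus: tuple[str, int] | None = None

    def __post_init__(self) -> None:
        self.markers = self.markers.reset_index(drop=True)
        if list(self.calls.columns) != list(self.markers["marker_id"]):
            raise ValueError("calls columns must match marker map order")
        vals = self.calls.to_numpy(dtype=float)
        ok = np.isnan(vals) | (vals == P1) | (vals == P2)
        if not ok.all():
            raise ValueError("genotype calls must be 0, 1 or NaN (homozygous biallelic)")
        _check_positions_increasing(self.markers)
        if self.selected_locus is not None:
            idx = self.nearest_marker(*self.selected_locus)
            col = self.markers.at[idx, "marker_id"]
            if not (self.calls[col] == P1).all():
                raise ValueError("selected locus is not fixed for P1 in all strains")

    @property
    def strains(self) -> list[str]:
        return list(self.calls.index)

    @property
    def n_markers(self) -> int:
        return len(self.markers)

    def nearest_marker(self, chrom: str, pos_bp: int) -> int:
        """Positional index of the marker nearest ``(chrom, pos_bp)``."""
        sub = self.markers[self.markers["chrom"] == chrom]
        if sub.empty:
            raise ValueError(f"no markers on chromosome {chrom!r}")
        return int((sub["pos_bp"] - pos_bp).abs().idxmin())

    def subset_markers(self, keep: np.ndarray) -> "GenotypeMatrix":
        """New matrix restricted to marker positional indices ``keep`` (in order)."""
        markers = self.markers.iloc[keep].reset_index(drop=True)
        calls = self.calls.iloc[:, keep]
        return GenotypeMatrix(calls=calls, markers=markers, selected_locus=None)


@dataclass
class ExpressionMatrix:
    """Log2 expression of array spots (features) across strains.

    ``features`` carries one row per spot: ``spot_id``, ``gene_id``,
    ``chrom``, ``pos_bp``; a spot with missing ``chrom`` is unplaced.  A
    gene may be represented by several spots.  ``parental_values`` holds
    replicate profiles of the two parents (columns named in
    ``parental_genotype``, mapping column -> "P1" or "P2").
    """

    features: pd.DataFrame
    values: pd.DataFrame
    parental_values: pd.DataFrame | None = None
    parental_genotype: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.features = self.features.reset_index(drop=True)
        if self.features["spot_id"].duplicated().any():
            dup = self.features.loc[self.features["spot_id"].duplicated(), "spot_id"].iloc[0]
            raise ValueError(f"duplicated spot id {dup!r}")
        if list(self.values.index) != list(self.features["spot_id"]):
            raise ValueError("values index must match features spot_id order")
        if self.values.isna().any().any():
            raise ValueError("expression matrix contains missing strain values")
        if self.parental_values is not None:
            bad = set(self.parental_values.columns) - set(self.parental_genotype)
            if bad:
                raise ValueError(f"parental columns without genotype label: {sorted(bad)}")

    @property
    def strains(self) -> list[str]:
        return list(self.values.columns)

    def parent_means(self) -> pd.DataFrame:
        """Per-spot mean profile of each parent; columns ``P1`` and ``P2``."""
        if self.parental_values is None or not self.parental_genotype:
            raise ValueError("expression matrix has no parental profile columns")
        out = {}
        for geno in ("P1", "P2"):
            cols = [c for c, g in self.parental_genotype.items() if g == geno]
            if not cols:
                raise ValueError(f"no parental replicate columns labelled {geno}")
            out[geno] = self.parental_values[cols].mean(axis=1)
        return pd.DataFrame(out)


@dataclass
class TrueArchitecture:
    """Planted truth table for a simulated expression data set.

    ``features`` mirrors :class:`ExpressionMatrix.features`.  ``effects``
    has one row per planted effect: ``spot_id``, ``marker_id``, ``effect``
    (in noise-SD units, positive = higher in P1/N2), ``kind`` in
    {``cis``, ``trans``, ``transband``} and ``band_id`` (empty string when
    not part of a band).
    """

    features: pd.DataFrame
    effects: pd.DataFrame
    noise_sd: float = 1.0
    baseline: float = 8.0

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        missing = {"spot_id", "marker_id", "effect", "kind", "band_id"} - set(
            self.effects.columns
        )
        if missing:
            raise ValueError(f"effects table missing columns {sorted(missing)}")


@dataclass
class ReferenceCisPanel:
    """Reference panel of signed cis-eQTL effects used as genotyping probes.

    One row per gene: ``gene_id``, ``chrom``, ``pos_bp``, ``effect``.  The
    sign convention is positive = higher expression on the P1 (N2) allele;
    correlating a strain's parental-centred profile against these effects
    therefore yields positive r for P1 genotypes.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        missing = {"gene_id", "chrom", "pos_bp", "effect"} - set(self.table.columns)
        if missing:
            raise ValueError(f"panel missing columns {sorted(missing)}")
        eff = self.table["effect"].to_numpy(dtype=float)
        if not np.all(np.isfinite(eff)) or np.any(eff == 0):
            raise ValueError("panel effects must be finite and nonzero")
        t = self.table.sort_values(["chrom", "pos_bp"], kind="stable").reset_index(drop=True)
        self.table = t

    def __len__(self) -> int:
        return len(self.table)
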