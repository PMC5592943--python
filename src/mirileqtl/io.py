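"""TSV formats, pipeline configuration and the end-to-end runner.

All tables are tab-delimited UTF-8 with ``#`` comment lines and 1-based
inclusive genomic coordinates.  Numeric output uses 6 significant digits
so reruns diff clean.

Formats
-------
genotype
    rows = strains, columns = marker ids, cells in {P1, P2, NA}; a
    sidecar ``<stem>.markers.tsv`` holds marker_id, chrom, pos_bp.
expression
    columns spot_id, gene_id, chrom, pos_bp then one column per strain;
    parental replicate columns are declared in ``#parental`` comments.
panel
    gene_id, chrom, pos_bp, effect (positive = higher in P1/N2).
eqtl
    spot_id, gene_id, gene_chrom, gene_pos, peak_chrom, peak_pos,
    neg_log10_p, effect, ci_start, ci_end, class.
annotation
    category_id, gene_id.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import enrichment, genetic_map, hotspots, mapping, significance, simulate
from .containers import ExpressionMatrix, GenotypeMatrix, ReferenceCisPanel

logger = logging.getLogger(__name__)

FLOAT_FORMAT = "%.6g"
_CALL_TO_TEXT = {1.0: "P1", 0.0: "P2"}
_TEXT_TO_CALL = {"P1": 1.0, "P2": 0.0, "NA": np.nan}


def write_genotypes(genotypes: GenotypeMatrix, path: str | Path) -> None:
    path = Path(path)
    txt = genotypes.calls.map(
        lambda v: "NA" if pd.isna(v) else _CALL_TO_TEXT[float(v)]
    )
    txt.index.name = "strain"
    txt.to_csv(path, sep="\t")
    genotypes.markers.to_csv(path.with_suffix(".markers.tsv"), sep="\t", index=False)


def read_genotypes(path: str | Path) -> GenotypeMatrix:
    path = Path(path)
    txt = pd.read_csv(path, sep="\t", index_col=0, comment="#", dtype=str)
    if txt.index.duplicated().any():
        dup = txt.index[txt.index.duplicated()][0]
        raise ValueError(f"{path}: duplicate strain id {dup!r}")
    bad = set(np.unique(txt.to_numpy().astype(str))) - set(_TEXT_TO_CALL) - {"nan"}
    if bad:
        raise ValueError(
            f"{path}: invalid genotype codes {sorted(bad)} (heterozygous or malformed calls)"
        )
    calls = txt.map(_TEXT_TO_CALL.get).astype(float)
    markers = pd.read_csv(
        path.with_suffix(".markers.tsv"), sep="\t", comment="#", dtype={"chrom": str}
    )
    return GenotypeMatrix(calls=calls, markers=markers)


def write_expression(expression: ExpressionMatrix, path: str | Path) -> None:
    path = Path(path)
    body = pd.concat(
        [expression.features.set_index("spot_id"), expression.values], axis=1
    )
    with open(path, "w") as fh:
        for col, geno in expression.parental_genotype.items():
            fh.write(f"#parental\t{col}\t{geno}\n")
        if expression.parental_values is not None:
            body = pd.concat([body, expression.parental_values], axis=1)
        body.index.name = "spot_id"
        body.to_csv(fh, sep="\t", float_format=FLOAT_FORMAT)


def read_expression(path: str | Path) -> ExpressionMatrix:
    path = Path(path)
    parental_genotype: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            parts = line.rstrip("\n").split("\t")
            if parts[0] == "#parental" and len(parts) == 3:
                parental_genotype[parts[1]] = parts[2]
    tab = pd.read_csv(path, sep="\t", comment="#", dtype={"chrom": str})
    if tab["spot_id"].duplicated().any():
        dup = tab.loc[tab["spot_id"].duplicated(), "spot_id"].iloc[0]
        raise ValueError(f"{path}: duplicated spot id {dup!r}")
    meta_cols = ["spot_id", "gene_id", "chrom", "pos_bp"]
    missing = set(meta_cols) - set(tab.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    strain_cols = [c for c in tab.columns if c not in meta_cols and c not in parental_genotype]
    non_numeric = [
        c for c in strain_cols if not np.issubdtype(tab[c].dtype, np.number)
    ]
    if non_numeric:
        raise ValueError(f"{path}: non-numeric expression columns {non_numeric}")
    values = tab[strain_cols]
    values.index = tab["spot_id"]
    parental = None
    if parental_genotype:
        parental = tab[list(parental_genotype)]
        parental.index = tab["spot_id"]
    return ExpressionMatrix(
        features=tab[meta_cols].copy(),
        values=values,
        parental_values=parental,
        parental_genotype=parental_genotype,
    )


def write_panel(panel: ReferenceCisPanel, path: str | Path) -> None:
    panel.table.to_csv(path, sep="\t", index=False, float_format=FLOAT_FORMAT)


def read_panel(path: str | Path) -> ReferenceCisPanel:
    return ReferenceCisPanel(
        table=pd.read_csv(path, sep="\t", comment="#", dtype={"chrom": str})
    )


def write_eqtl(records: pd.DataFrame, path: str | Path) -> None:
    records.to_csv(path, sep="\t", index=False, float_format=FLOAT_FORMAT)


def read_eqtl(path: str | Path) -> pd.DataFrame:
    tab = pd.read_csv(
        path, sep="\t", comment="#", dtype={"gene_chrom": str, "peak_chrom": str}
    )
    missing = set(mapping.EQTL_COLUMNS) - set(tab.columns)
    if missing:
        raise ValueError(f"{path}: missing eQTL columns {sorted(missing)}")
    return tab


def read_annotation(path: str | Path) -> pd.DataFrame:
    tab = pd.read_csv(path, sep="\t", comment="#")
    missing = {"category_id", "gene_id"} - set(tab.columns)
    if missing:
        raise ValueError(f"{path}: missing annotation columns {sorted(missing)}")
    return tab


def load_matrix(path: str | Path, kind: str):
    """Load a typed table: genotype | expression | panel | eqtl | annotation."""
    loaders = {
        "genotype": read_genotypes,
        "expression": read_expression,
        "panel": read_panel,
        "eqtl": read_eqtl,
        "annotation": read_annotation,
    }
    if kind not in loaders:
        raise ValueError(f"unknown matrix kind {kind!r}")
    if not Path(path).exists():
        raise FileNotFoundError(path)
    return loaders[kind](path)


@dataclass
class PipelineConfig:
    """All stage parameters; defaults are the study's parameter set."""

    # inputs (simulated when absent)
    genotype_path: str | None = None
    expression_path: str | None = None
    panel_path: str | None = None
    reference_paths: list[str] = field(default_factory=list)
    annotation_path: str | None = None
    outdir: str = "mirileqtl_run"
    # synthetic population
    n_lines: int = 33
    n_features: int = 5000
    n_panel_genes: int = 8480
    # genetic map from expression
    window: int = 20
    call_threshold: float = 0.6
    qc_threshold: float = 0.5
    min_fraction_called: float = 0.5
    min_minor_freq: float = 0.15
    # mapping
    cis_window: int = 2_000_000
    ci_drop: float = 1.5
    # significance
    q: float = 0.1
    n_perm: int = 10
    threshold: float | None = None  # override: skip permutations when set
    # hotspots
    bin_size: int = 1_000_000
    sig_level: float = 0.001
    # power
    reps_per_marker: int = 10
    seed: int = 0

    def validate(self) -> None:
        if self.q <= 0:
            raise ValueError("q must be > 0")
        if self.n_perm < 1:
            raise ValueError("n_perm must be >= 1")
        if self.window < 2:
            raise ValueError("window must be >= 2")
        if self.threshold is not None and self.threshold <= 0:
            raise ValueError("threshold override must be > 0")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        unknown = set(data) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise ValueError(f"unknown config keys {sorted(unknown)}")
        return cls(**data)


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the full pipeline and write stage TSVs plus a JSON run report.

    Stages: simulate (or load) genotypes/expression -> expression-marker
    genotyping -> informative-marker pruning -> scan -> permutation
    threshold -> peak calling -> cis/trans classification -> trans-band
    detection -> optional replication and enrichment.  Deterministic for
    a fixed config and seed.
    """
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report: dict = {"parameters": dataclasses.asdict(config), "counts": {}}
    rng = np.random.default_rng(config.seed)

    def stage_seed() -> int:
        return int(rng.integers(0, 2**31 - 1))

    try:
        if config.genotype_path:
            true_genotypes = load_matrix(config.genotype_path, "genotype")
        else:
            true_genotypes = simulate.simulate_miril_genotypes(
                n_lines=config.n_lines, seed=stage_seed()
            )
            write_genotypes(true_genotypes, outdir / "genotypes_true.tsv")
        if config.panel_path:
            panel = load_matrix(config.panel_path, "panel")
        else:
            panel = simulate.simulate_reference_cis_panel(
                true_genotypes, n_genes=config.n_panel_genes, seed=stage_seed()
            )
            write_panel(panel, outdir / "reference_panel.tsv")
        if config.expression_path:
            expression = load_matrix(config.expression_path, "expression")
        else:
            architecture = simulate.plant_architecture(
                true_genotypes,
                n_features=config.n_features,
                panel=panel,
                seed=stage_seed(),
            )
            architecture.effects.to_csv(
                outdir / "true_architecture.tsv", sep="\t", index=False,
                float_format=FLOAT_FORMAT,
            )
            expression = simulate.simulate_expression(
                true_genotypes, architecture, seed=stage_seed()
            )
            write_expression(expression, outdir / "expression.tsv")
    except Exception as exc:
        raise RuntimeError(f"stage 'simulate/load' failed: {exc}") from exc

    try:
        centered = genetic_map.center_on_parents(expression)
        calls = genetic_map.call_expression_markers(
            centered, panel, window=config.window, call_threshold=config.call_threshold
        )
        calls_qc = genetic_map.qc_filter_markers(
            calls,
            expression.parental_genotype,
            min_fraction_called=config.min_fraction_called,
            qc_threshold=config.qc_threshold,
        )
        imputed, _provenance = genetic_map.impute_and_extend(calls_qc)
        genotypes, _corr = genetic_map.prune_informative_markers(
            imputed, min_minor_freq=config.min_minor_freq
        )
        write_genotypes(genotypes, outdir / "genotypes_expression_markers.tsv")
        report["counts"]["markers_called"] = int(calls["window_id"].nunique())
        report["counts"]["markers_qc"] = int(calls_qc["window_id"].nunique())
        report["counts"]["markers_informative"] = genotypes.n_markers
    except Exception as exc:
        raise RuntimeError(f"stage 'genotype' failed: {exc}") from exc

    try:
        if config.threshold is not None:
            threshold = config.threshold
        else:
            thr = significance.permutation_threshold(
                expression,
                genotypes,
                q=config.q,
                n_perm=config.n_perm,
                seed=stage_seed(),
            )
            thr.curve_table().to_csv(
                outdir / "threshold_curves.tsv", sep="\t", index=False,
                float_format=FLOAT_FORMAT,
            )
            if thr.threshold is None:
                raise RuntimeError("no cutoff satisfies the FDR criterion")
            threshold = thr.threshold
        report["threshold"] = threshold
    except Exception as exc:
        raise RuntimeError(f"stage 'threshold' failed: {exc}") from exc

    try:
        scanm = mapping.scan(expression, genotypes)
        records = mapping.call_peaks(
            scanm, expression.features, threshold=threshold, ci_drop=config.ci_drop
        )
        records = mapping.classify_cis_trans(records, cis_window=config.cis_window)
        write_eqtl(records, outdir / "eqtl.tsv")
        counts = mapping.summarize_counts(records)
        counts.to_csv(outdir / "eqtl_counts.tsv", sep="\t", index=False)
        for _, row in counts.iterrows():
            report["counts"][f"{row['class']}_{row['sign']}_genes"] = int(row["n_genes"])
            report["counts"][f"{row['class']}_{row['sign']}_spots"] = int(row["n_spots"])
    except Exception as exc:
        raise RuntimeError(f"stage 'scan' failed: {exc}") from exc

    try:
        trans = records[records["class"] == "trans"]
        bands, lam = hotspots.detect_trans_bands(
            trans, bin_size=config.bin_size, sig_level=config.sig_level
        )
        band_tab = pd.DataFrame(
            [
                (b.label, b.chrom, b.start_mb, b.end_mb, b.n_spots, b.n_genes, b.lam, b.p_value)
                for b in bands
            ],
            columns=["band", "chrom", "start_mb", "end_mb", "n_spots", "n_genes", "lambda", "p_value"],
        )
        band_tab.to_csv(
            outdir / "trans_bands.tsv", sep="\t", index=False, float_format=FLOAT_FORMAT
        )
        report["lambda_per_bin"] = None if np.isnan(lam) else lam
        report["counts"]["trans_bands"] = len(bands)
    except Exception as exc:
        raise RuntimeError(f"stage 'hotspots' failed: {exc}") from exc

    if config.reference_paths:
        try:
            refs = [load_matrix(p, "eqtl") for p in config.reference_paths]
            rep = hotspots.replication_overlap(records, refs)
            report["replication"] = {
                "cis_rate": rep.cis_rate,
                "trans_rate": rep.trans_rate,
            }
            if bands:
                uniq = hotspots.band_uniqueness_table(bands, records, rep)
                uniq.to_csv(
                    outdir / "band_uniqueness.tsv", sep="\t", index=False,
                    float_format=FLOAT_FORMAT,
                )
        except Exception as exc:
            raise RuntimeError(f"stage 'replication' failed: {exc}") from exc

    if config.annotation_path:
        try:
            ann = load_matrix(config.annotation_path, "annotation")
            universe = set(expression.features["gene_id"])
            query = set(trans["gene_id"])
            res = enrichment.enrich(query, ann, universe)
            enrichment.enrichment_table(res).to_csv(
                outdir / "enrichment.tsv", sep="\t", index=False,
                float_format=FLOAT_FORMAT,
            )
            report["counts"]["enriched_categories"] = sum(r.passed for r in res)
        except Exception as exc:
            raise RuntimeError(f"stage 'enrich' failed: {exc}") from exc

    with open(outdir / "run_report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
    return report
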