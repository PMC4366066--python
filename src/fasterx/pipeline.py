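"""End-to-end orchestration: input parsing, the analysis battery, and
report generation. The only module that touches the filesystem.

A run consumes either the five real-data inputs (annotation TSV,
expression TSV, tissue matrix TSV, interaction edge list TSV, two FASTA
files of codon-aligned CDS) or a simulation configuration, never a mix.
Every input gene ends the run with exactly one disposition: "analyzed"
or "excluded:<reason>".
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO

from . import codonevol, exprprops, stats
from .codonevol import CodonSequencePair
from .simdata import SimulationConfig, SyntheticDataset, generate_dataset

RESPONSES = ("expression_divergence", "expression_polymorphism", "dN", "dS", "omega")
GENE_CLASSES = ("MBG", "NBG", "all")


@dataclass
class AnalysisConfig:
    # real-data inputs (all five required together)
    annotation_path: str | None = None
    expression_path: str | None = None
    tissue_path: str | None = None
    interactions_path: str | None = None
    fasta_a_path: str | None = None
    fasta_b_path: str | None = None
    # or a simulation in lieu of them
    simulation: SimulationConfig | None = None
    # thresholds
    min_depth: int = 7
    min_quality: float = 40.0
    omega_cap: float = 9.0
    sex_bias_log2_threshold: float = 1.0
    n_bins: int = 10
    method: str = "ml"  # "ng86", "ml" or "both"
    sidedness: str = "two"
    outdir: str = "fasterx_out"
    seed: int = 0

    def validate(self) -> None:
        paths = [
            self.annotation_path,
            self.expression_path,
            self.tissue_path,
            self.interactions_path,
            self.fasta_a_path,
            self.fasta_b_path,
        ]
        have_paths = [p is not None for p in paths]
        if self.simulation is not None and any(have_paths):
            raise ValueError("provide either real-data paths or a simulation config, not both")
        if self.simulation is None and not all(have_paths):
            raise ValueError("real-data mode requires all five input paths")
        if self.method not in ("ng86", "ml", "both"):
            raise ValueError(f"unknown method {self.method!r}")


@dataclass
class InputBundle:
    gene_table: pd.DataFrame  # annotation, indexed by gene_id
    measurements: pd.DataFrame
    tissue_matrix: pd.DataFrame
    edges: list
    codon_pairs: dict
    dispositions: dict = field(default_factory=dict)  # gene_id -> excluded:<reason>


@dataclass
class ReportBundle:
    master_table: pd.DataFrame
    test_results: pd.DataFrame
    regression_table: pd.DataFrame
    correlation_table: pd.DataFrame
    stratified_table: pd.DataFrame
    metadata: dict
    failures: list = field(default_factory=list)


# ---------------------------------------------------------------------------
# parsing
# ---------------------------------------------------------------------------

def _read_tsv(path, required_cols, name):
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in required_cols if c not in df.columns]
    if missing:
        raise ValueError(f"{name} file {path}: missing columns {missing}")
    return df


def _check_unique(df, col, path):
    dup = df[col][df[col].duplicated()]
    if len(dup):
        # +2: header line plus 1-based numbering
        line = int(df.index[df[col] == dup.iloc[0]][1]) + 2
        raise ValueError(f"duplicate gene ID {dup.iloc[0]!r} in {path} at line {line}")


def read_fasta_sequences(path) -> dict:
    seqs = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seqs:
            raise ValueError(f"duplicate gene ID {rec.id!r} in {path}")
        seqs[rec.id] = str(rec.seq).upper()
    return seqs


def read_config_file(path) -> dict:
    """Flat ``key = value`` text config; '#' starts a comment."""
    out = {}
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ValueError(f"{path}:{lineno}: expected 'key = value', got {raw!r}")
        key, value = (s.strip() for s in line.split("=", 1))
        out[key] = value
    return out


def read_inputs(config: AnalysisConfig) -> InputBundle:
    """Load and reconcile the five inputs (or generate them).

    Genes missing from a required input are recorded with disposition
    ``excluded:missing_<input>``; a FASTA ID present in only one species
    is recorded as missing its ortholog, not fatal.
    """
    config.validate()
    if config.simulation is not None:
        return inputs_from_dataset(generate_dataset(config.simulation))

    ann = _read_tsv(config.annotation_path, ["gene_id", "chromosome"], "annotation")
    _check_unique(ann, "gene_id", config.annotation_path)
    ann = ann.set_index("gene_id")
    expr = _read_tsv(
        config.expression_path, exprprops.EXPRESSION_COLUMNS, "expression"
    )
    tissue = pd.read_csv(config.tissue_path, sep="\t")
    if "gene_id" not in tissue.columns:
        raise ValueError(f"tissue matrix {config.tissue_path}: missing gene_id column")
    _check_unique(tissue, "gene_id", config.tissue_path)
    tissue = tissue.set_index("gene_id")
    inter = _read_tsv(
        config.interactions_path, ["gene_a", "gene_b"], "interactions"
    )
    edges = list(zip(inter["gene_a"], inter["gene_b"]))
    seqs_a = read_fasta_sequences(config.fasta_a_path)
    seqs_b = read_fasta_sequences(config.fasta_b_path)

    dispositions = {}
    expr_genes = set(expr["gene_id"])
    pairs = {}
    for gid in ann.index:
        if gid not in expr_genes:
            dispositions[gid] = "excluded:missing_expression"
            continue
        in_a, in_b = gid in seqs_a, gid in seqs_b
        if in_a and in_b:
            pairs[gid] = CodonSequencePair(gid, seqs_a[gid], seqs_b[gid])
        elif in_a != in_b:
            dispositions[gid] = "excluded:missing_ortholog"
    return InputBundle(
        gene_table=ann,
        measurements=expr,
        tissue_matrix=tissue,
        edges=edges,
        codon_pairs=pairs,
        dispositions=dispositions,
    )


def inputs_from_dataset(ds: SyntheticDataset) -> InputBundle:
    ann = ds.gene_table[["chromosome", "bias_class"]].copy()
    return InputBundle(
        gene_table=ann,
        measurements=ds.measurements,
        tissue_matrix=ds.tissue_matrix,
        edges=list(ds.interaction_edges),
        codon_pairs=dict(ds.codon_pairs),
    )


# ---------------------------------------------------------------------------
# analysis
# ---------------------------------------------------------------------------

def _degree_series(edges, gene_index) -> pd.Series:
    deg = pd.Series(0, index=gene_index, dtype=int)
    for a, b in edges:
        if a in deg.index:
            deg[a] += 1
        if b in deg.index:
            deg[b] += 1
    return deg


def build_master_table(config: AnalysisConfig, inputs: InputBundle):
    """Per-gene covariates, divergence estimates, QC flags and
    dispositions; returns (master DataFrame, divergence estimates dict)."""
    genes = inputs.gene_table.index
    master = inputs.gene_table.copy()
    master["disposition"] = [
        inputs.dispositions.get(g, "analyzed") for g in genes
    ]

    summaries = exprprops.summarize_expression_table(inputs.measurements)
    master = master.join(
        summaries.rename(
            columns={
                "divergence": "expression_divergence",
                "polymorphism": "expression_polymorphism",
            }
        )
    )
    tau = exprprops.tissue_specificity_table(
        inputs.tissue_matrix.reindex(genes).fillna(0.0)
    )
    in_tissue = inputs.tissue_matrix.index
    tau[~genes.isin(in_tissue)] = np.nan
    master["tau"] = tau
    master["degree"] = _degree_series(inputs.edges, genes)

    if "bias_class" not in master.columns:
        if {"male_level", "female_level"}.issubset(master.columns):
            master["bias_class"] = [
                exprprops.classify_sex_bias(m, f, config.sex_bias_log2_threshold)
                for m, f in zip(master["male_level"], master["female_level"])
            ]
        else:
            raise ValueError(
                "annotation needs either a bias_class column or male_level/female_level"
            )

    # divergence estimation + gene filters
    estimates = {}
    qc_reports = []
    methods = {"ng86": ["NG86"], "ml": ["ML_M0"], "both": ["NG86", "ML_M0"]}[config.method]
    for col in ("dN", "dS", "omega", "kappa", "t"):
        master[col] = np.nan
    master["qc_flags"] = ""
    est_for_filter = []
    for gid in genes:
        pair = inputs.codon_pairs.get(gid)
        if pair is None:
            if master.at[gid, "disposition"] == "analyzed":
                master.at[gid, "disposition"] = "excluded:missing_sequence"
            continue
        rep = codonevol.validate_cds(pair)
        qc_reports.append(rep)
        flags = []
        if rep.length_error:
            flags.append("length_error")
        if rep.internal_stop_a:
            flags.append("internal_stop_a")
        if rep.internal_stop_b:
            flags.append("internal_stop_b")
        master.at[gid, "qc_flags"] = ";".join(flags)
        if not rep.ok:
            reason = "length_error" if rep.length_error else "internal_stop"
            master.at[gid, "disposition"] = f"excluded:{reason}"
            continue
        per_gene = {}
        for m in methods:
            est = (
                codonevol.ng86(pair)
                if m == "NG86"
                else codonevol.gy94_ml(pair)
            )
            per_gene[m] = est
        primary = per_gene.get("ML_M0", per_gene.get("NG86"))
        estimates[gid] = per_gene
        est_for_filter.append(primary)
        master.at[gid, "dN"] = primary.dN
        master.at[gid, "dS"] = primary.dS
        master.at[gid, "omega"] = primary.omega
        master.at[gid, "kappa"] = primary.kappa
        master.at[gid, "t"] = primary.t

    filt = codonevol.apply_divergence_filters(
        est_for_filter, qc_reports, omega_cap=config.omega_cap
    )
    for gid, reason in filt.excluded.items():
        if master.at[gid, "disposition"] == "analyzed":
            master.at[gid, "disposition"] = f"excluded:{reason}"

    # property-complete subset: every covariate defined and gene analyzed
    prop_cols = ["level", "tau", "degree", "expression_divergence"]
    master["property_complete"] = (
        master[prop_cols].notna().all(axis=1) & (master["disposition"] == "analyzed")
    )
    return master, estimates


def _class_mask(master: pd.DataFrame, gene_class: str) -> pd.Series:
    if gene_class == "all":
        return pd.Series(True, index=master.index)
    return master["bias_class"] == gene_class


def run_statistics(config: AnalysisConfig, master: pd.DataFrame) -> tuple:
    """The statistical battery over gene classes and responses.

    Returns tidy DataFrames: test results, regression parameters
    (one row per class x response), Spearman correlations, and the
    stratified-comparison summaries.
    """
    test_rows, reg_rows, corr_rows, strat_rows = [], [], [], []
    covars = {"Lev": "level", "Spe": "tau", "Int": "degree"}
    usable = master[master["property_complete"]].copy()

    for response in RESPONSES:
        if response not in usable.columns:
            continue
        for gene_class in GENE_CLASSES:
            sub = usable[_class_mask(usable, gene_class)].dropna(subset=[response])
            n_x = int((sub["chromosome"] == "X").sum())
            n_a = int((sub["chromosome"] == "A").sum())
            if n_x < 3 or n_a < 3 or len(sub) < 10:
                continue
            base = {"response": response, "gene_class": gene_class, "n": len(sub)}

            mw = stats.mann_whitney_u(
                sub.loc[sub["chromosome"] == "X", response],
                sub.loc[sub["chromosome"] == "A", response],
                sidedness=config.sidedness,
            )
            test_rows.append(
                base
                | {
                    "test": "xa_mann_whitney",
                    "statistic_name": "U",
                    "statistic": mw.statistic,
                    "p_value": mw.p_value,
                    "detail": f"n_X={n_x},n_A={n_a}",
                }
            )

            for label, col in covars.items():
                sr = stats.spearman_rho(sub[col], sub[response])
                corr_rows.append(
                    base
                    | {
                        "covariate": label,
                        "rho": sr.statistic,
                        "p_value": sr.p_value,
                    }
                )

            cov_data = {k: sub[c].to_numpy(dtype=float) for k, c in covars.items()}
            try:
                fit = stats.fit_standardized_ols(sub[response].to_numpy(), cov_data)
            except ValueError as exc:
                reg_rows.append(base | {"error": str(exc)})
                continue
            row = base | {"R": fit.r_multiple, "R_p": fit.model_p}
            for k in covars:
                row[f"b_{k}"] = fit.coefficients[k]
                row[f"b_{k}_p"] = fit.coefficient_p[k]
            reg_rows.append(row)

            rt = stats.residual_group_test(
                fit, sub["chromosome"].to_numpy(), sidedness=config.sidedness
            )
            test_rows.append(
                base
                | {
                    "test": "residual_mann_whitney",
                    "statistic_name": "U",
                    "statistic": rt.statistic,
                    "p_value": rt.p_value,
                    "detail": f"n_X={n_x},n_A={n_a}",
                }
            )

            try:
                sc = stats.stratified_xa_comparison(
                    sub[response].to_numpy(),
                    {k: sub[c].to_numpy(dtype=float) for k, c in covars.items()},
                    sub["chromosome"].to_numpy(),
                    n_bins=config.n_bins,
                    sidedness=config.sidedness,
                )
            except ValueError:
                continue
            test_rows.append(
                base
                | {
                    "test": "stratified_wilcoxon",
                    "statistic_name": "T",
                    "statistic": sc.test.statistic,
                    "p_value": sc.test.p_value,
                    "detail": f"n_categories={sc.n_categories_retained}",
                }
            )
            strat_rows.append(
                base
                | {
                    "n_categories": sc.n_categories_retained,
                    "mean_difference": float(np.mean(sc.differences)),
                    "T": sc.test.statistic,
                    "p_value": sc.test.p_value,
                }
            )

    return (
        pd.DataFrame(test_rows),
        pd.DataFrame(reg_rows),
        pd.DataFrame(corr_rows),
        pd.DataFrame(strat_rows),
    )


def run_analysis(config: AnalysisConfig) -> ReportBundle:
    """Full pipeline: inputs -> expression and divergence properties ->
    filters -> statistical battery -> report bundle."""
    config.validate()
    inputs = read_inputs(config)
    failures = []
    master, _ = build_master_table(config, inputs)
    try:
        tests, regs, corrs, strats = run_statistics(config, master)
    except Exception as exc:  # a stage failure yields a partial bundle
        failures.append(f"statistics: {exc}")
        tests = regs = corrs = strats = pd.DataFrame()
    sim = config.simulation
    metadata = {
        "seed": config.seed,
        "mode": "simulation" if sim is not None else "real",
        "n_genes": int(len(master)),
        "n_analyzed": int((master["disposition"] == "analyzed").sum()),
        "n_property_complete": int(master["property_complete"].sum()),
        "config": _jsonable(dataclasses.asdict(config)),
    }
    return ReportBundle(
        master_table=master,
        test_results=tests,
        regression_table=regs,
        correlation_table=corrs,
        stratified_table=strats,
        metadata=metadata,
        failures=failures,
    )


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer, np.floating)):
        return obj.item()
    if isinstance(obj, float) and math.isnan(obj):
        return None
    return obj


# ---------------------------------------------------------------------------
# report writing
# ---------------------------------------------------------------------------

_TABLES = {
    "master_table.tsv": "master_table",
    "test_results.tsv": "test_results",
    "regression_table.tsv": "regression_table",
    "correlation_table.tsv": "correlation_table",
    "stratified_table.tsv": "stratified_table",
}


def _format_table(df: pd.DataFrame) -> str:
    # '.' decimal separator, no thousands separators, scientific
    # notation for small values (covers P < 1e-4)
    return df.to_csv(sep="\t", index=df.index.name is not None, float_format="%.6g")


def write_report(bundle: ReportBundle, outdir, force: bool = False) -> dict:
    """Write the report tables, run metadata and a checksum manifest.

    Refuses to overwrite an existing report unless ``force``.
    Returns the manifest (filename -> sha256 of content).
    """
    out = Path(outdir)
    manifest_path = out / "manifest.tsv"
    if manifest_path.exists() and not force:
        raise FileExistsError(f"{out} already contains a report; use force=True to overwrite")
    out.mkdir(parents=True, exist_ok=True)
    manifest = {}
    for fname, attr in _TABLES.items():
        df = getattr(bundle, attr)
        text = _format_table(df if isinstance(df, pd.DataFrame) else pd.DataFrame())
        (out / fname).write_text(text)
        manifest[fname] = hashlib.sha256(text.encode()).hexdigest()
    meta = dict(bundle.metadata)
    if bundle.failures:
        meta["failures"] = bundle.failures
    meta_text = json.dumps(meta, indent=2, sort_keys=True, default=str) + "\n"
    (out / "run_metadata.json").write_text(meta_text)
    manifest["run_metadata.json"] = hashlib.sha256(meta_text.encode()).hexdigest()
    lines = ["file\tsha256"] + [f"{k}\t{v}" for k, v in sorted(manifest.items())]
    manifest_path.write_text("\n".join(lines) + "\n")
    return manifest


def verify_report(outdir) -> dict:
    """Recompute checksums of an existing report; returns
    filename -> bool (matches manifest)."""
    out = Path(outdir)
    lines = (out / "manifest.tsv").read_text().splitlines()[1:]
    status = {}
    for line in lines:
        fname, digest = line.split("\t")
        actual = hashlib.sha256((out / fname).read_bytes()).hexdigest()
        status[fname] = actual == digest
    return status


def write_simulation_inputs(ds: SyntheticDataset, outdir, force: bool = False) -> list:
    """Write a synthetic dataset in the real-data input formats:
    gene_table.tsv, expression.tsv, tissue_matrix.tsv, interactions.tsv,
    species1.fa, species2.fa. Returns the list of files written."""
    out = Path(outdir)
    targets = [
        "gene_table.tsv",
        "expression.tsv",
        "tissue_matrix.tsv",
        "interactions.tsv",
        "species1.fa",
        "species2.fa",
    ]
    if not force:
        for t in targets:
            if (out / t).exists():
                raise FileExistsError(f"{out / t} exists; use force=True to overwrite")
    out.mkdir(parents=True, exist_ok=True)
    ds.gene_table.reset_index().to_csv(out / "gene_table.tsv", sep="\t", index=False)
    ds.measurements.to_csv(out / "expression.tsv", sep="\t", index=False)
    ds.tissue_matrix.reset_index().to_csv(out / "tissue_matrix.tsv", sep="\t", index=False)
    pd.DataFrame(ds.interaction_edges, columns=["gene_a", "gene_b"]).to_csv(
        out / "interactions.tsv", sep="\t", index=False
    )
    for fname, attr in (("species1.fa", "seq_a"), ("species2.fa", "seq_b")):
        with open(out / fname, "w") as fh:
            for gid in ds.gene_table.index:
                pair = ds.codon_pairs.get(gid)
                if pair is None:
                    continue
                fh.write(f">{gid}\n{getattr(pair, attr)}\n")
    return targets
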