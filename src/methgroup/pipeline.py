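"""Pipeline orchestration: YAML config, staged execution, JSON/Markdown report.

Stages communicate through files in the output directory so each one can be
re-run independently (`simulate` -> `cluster` -> `hmr`/`cnv` -> `de` ->
`enrich` -> `stats` -> `report`).  One master seed drives everything; each
stage derives its own child stream (see :mod:`methgroup.seeding`), so a
stage re-run reproduces the monolithic run exactly.
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

from . import clustering, cohort_stats, expression, io_formats, regions, synthetic
from .cohort import MethylationCohort, TruthLedger, load_methylation_cohort
from .seeding import stage_seed

logger = logging.getLogger("methgroup")

__all__ = ["PipelineConfig", "ConfigError", "StageError", "run", "STAGES"]


class ConfigError(ValueError):
    """Invalid or unknown configuration (CLI exit code 2)."""


class StageError(RuntimeError):
    """A pipeline stage failed (CLI exit code 3); names the stage."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"stage '{stage}': {message}")
        self.stage = stage


@dataclass
class ClusteringBlock:
    k_min: int = 2
    k_max: int = 6
    gap_k_min: int = 1
    H: int = 100
    p: float = 0.8
    B: int = 50
    n_top: int = 5_000
    n_restarts: int = 20
    gap_n_pcs: int = 10
    delta_threshold: float = 0.1
    embedding: str = "umap"
    n_neighbors: int = 15


@dataclass
class HmrBlock:
    tau: float = 0.3
    max_gap: int = 500
    min_cpgs: int = 4
    min_cov: int = 5


@dataclass
class CnvBlock:
    bin_size: int = 500_000
    t_threshold: float = 4.0
    min_bins: int = 5
    call_cutoff: float = 0.3


@dataclass
class DeBlock:
    fc_threshold: float = 1.0
    p_threshold: float = 0.05


@dataclass
class PipelineConfig:
    """Validated pipeline configuration (strict: unknown keys rejected)."""

    seed: int = 7
    inputs: str = "synthetic"  # "synthetic" or a directory of input files
    coverage_format: str = "bismark"
    synthetic: synthetic.SyntheticConfig = field(
        default_factory=synthetic.SyntheticConfig
    )
    clustering: ClusteringBlock = field(default_factory=ClusteringBlock)
    hmr: HmrBlock = field(default_factory=HmrBlock)
    cnv: CnvBlock = field(default_factory=CnvBlock)
    de: DeBlock = field(default_factory=DeBlock)
    output_dir: str = "methgroup_results"

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        def build(dc_type, obj, path):
            if not isinstance(obj, dict):
                raise ConfigError(f"{path}: expected a mapping")
            names = {f.name: f for f in dataclasses.fields(dc_type)}
            unknown = set(obj) - set(names)
            if unknown:
                raise ConfigError(f"{path}: unknown keys {sorted(unknown)}")
            kw = {}
            for key, val in obj.items():
                f = names[key]
                if dataclasses.is_dataclass(f.type) or f.name in (
                    "synthetic", "clustering", "hmr", "cnv", "de",
                ):
                    sub_type = {
                        "synthetic": synthetic.SyntheticConfig,
                        "clustering": ClusteringBlock,
                        "hmr": HmrBlock,
                        "cnv": CnvBlock,
                        "de": DeBlock,
                    }[f.name]
                    kw[key] = build(sub_type, val, f"{path}.{key}")
                else:
                    if isinstance(val, list):
                        val = tuple(val)
                    kw[key] = val
            try:
                return dc_type(**kw)
            except (TypeError, ValueError) as exc:
                raise ConfigError(f"{path}: {exc}") from None

        cfg = build(cls, raw or {}, "config")
        cfg.validate()
        return cfg

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls.from_dict(raw or {})

    def validate(self) -> None:
        c = self.clustering
        if not (1 <= c.k_min <= c.k_max):
            raise ConfigError("clustering: need 1 <= k_min <= k_max")
        if self.inputs == "synthetic":
            try:
                self.synthetic.validate()
            except ValueError as exc:
                raise ConfigError(f"synthetic: {exc}") from None
            if c.k_max > self.synthetic.n_samples:
                raise ConfigError("clustering.k_max exceeds n_samples")
        if c.H < 2:
            raise ConfigError("clustering.H must be >= 2")
        if not 0 < c.p <= 1:
            raise ConfigError("clustering.p must be in (0, 1]")
        if c.B < 2:
            raise ConfigError("clustering.B must be >= 2")
        if c.embedding not in ("pca", "umap", "tsne"):
            raise ConfigError(f"unknown embedding {c.embedding!r}")
        if not 0 < self.hmr.tau < 1:
            raise ConfigError("hmr.tau must be in (0, 1)")
        if self.cnv.bin_size <= 0 or self.cnv.min_bins < 1:
            raise ConfigError("cnv block: positive bin_size / min_bins required")
        if self.coverage_format not in ("bismark", "bedgraph"):
            raise ConfigError(f"unknown coverage format {self.coverage_format!r}")

    def echo(self, out_dir: Path) -> None:
        """Copy the effective config into the run directory for provenance."""
        obj = dataclasses.asdict(self)
        obj["synthetic"]["cnv_segments"] = {
            str(g): [list(s) for s in segs]
            for g, segs in obj["synthetic"]["cnv_segments"].items()
        }
        (out_dir / "config_used.yaml").write_text(
            yaml.safe_dump(obj, sort_keys=True)
        )


# ---------------------------------------------------------------------------
# stage helpers
# ---------------------------------------------------------------------------

def _require(path: Path, producer: str) -> Path:
    if not path.exists():
        raise StageError(
            producer, f"missing {path.name}; run the '{producer}' subcommand first"
        )
    return path


def _input_dir(config: PipelineConfig, out_dir: Path) -> Path:
    return out_dir if config.inputs == "synthetic" else Path(config.inputs)


def _load_cohort(config: PipelineConfig, out_dir: Path) -> MethylationCohort:
    src = _input_dir(config, out_dir)
    meta = io_formats.read_metadata(_require(src / "metadata.tsv", "simulate"))
    cov_dir = _require(src / "coverage", "simulate")
    paths = {s: cov_dir / f"{s}.cov" for s in meta["sample_id"]}
    for s, pth in paths.items():
        _require(Path(pth), "simulate")
    lengths = io_formats.read_chrom_lengths(_require(src / "genome.tsv", "simulate"))
    return load_methylation_cohort(
        paths, min_coverage=config.hmr.min_cov,
        fmt=config.coverage_format, chrom_lengths=lengths,
    )


def _load_labels(out_dir: Path) -> pd.DataFrame:
    path = _require(out_dir / "labels.tsv", "cluster")
    return pd.read_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------

def stage_simulate(config: PipelineConfig, out_dir: Path) -> dict:
    logger.info("simulate: seed=%d n_samples=%d", config.seed,
                config.synthetic.n_samples)
    artifacts = synthetic.generate_cohort(config.synthetic, config.seed)
    synthetic.write_cohort(artifacts, out_dir, fmt=config.coverage_format)
    return {"n_samples": config.synthetic.n_samples,
            "group_sizes": np.bincount(artifacts["truth"].labels)[1:].tolist()}


def stage_cluster(config: PipelineConfig, out_dir: Path) -> dict:
    c = config.clustering
    cohort = _load_cohort(config, out_dir)
    feats = clustering.select_features(cohort, n_top=c.n_top)
    logger.info("cluster: %d samples x %d features, seed=%d",
                feats.values.shape[0], feats.values.shape[1], config.seed)
    cons = clustering.consensus_cluster(
        feats, k_range=range(c.k_min, c.k_max + 1), H=c.H, p=c.p,
        seed=stage_seed(config.seed, "consensus"), n_restarts=c.n_restarts,
    )
    gap = clustering.gap_statistic(
        feats, k_range=range(c.gap_k_min, c.k_max + 1), B=c.B,
        seed=stage_seed(config.seed, "gap"), n_pcs=c.gap_n_pcs,
    )
    sel = clustering.select_k(cons, gap, delta_threshold=c.delta_threshold)
    labels = clustering.assign_groups(
        feats, sel.k_selected, seed=stage_seed(config.seed, "assign")
    )
    hier_labels, leaf_order = clustering.hierarchical_cluster(feats, sel.k_selected)
    coords = clustering.embed(
        feats, method=c.embedding, n_neighbors=c.n_neighbors,
        seed=stage_seed(config.seed, "embed"),
    )

    lab_df = pd.DataFrame(
        {"sample_id": feats.sample_ids, "group": labels,
         "hierarchical_group": hier_labels}
    )
    io_formats.write_table(lab_df, out_dir / "labels.tsv")
    io_formats.write_table(sel.diagnostics, out_dir / "k_diagnostics.tsv")
    emb_df = pd.DataFrame(
        {"sample_id": feats.sample_ids, "dim1": coords[:, 0], "dim2": coords[:, 1]}
    )
    io_formats.write_table(emb_df, out_dir / "embedding.tsv")
    pd.Series(leaf_order).to_csv(out_dir / "dendrogram_order.tsv", sep="\t",
                                 index=False, header=["leaf_order"])
    for k, C in cons.matrices.items():
        io_formats.write_table(
            pd.DataFrame(C, index=feats.sample_ids, columns=feats.sample_ids),
            out_dir / f"consensus_k{k}.tsv", index=True,
        )
    summary = {
        "k_selected": sel.k_selected, "k_gap": sel.k_gap,
        "k_delta": sel.k_delta, "concordant": sel.concordant,
    }
    truth_path = _input_dir(config, out_dir) / "truth.json"
    if truth_path.exists():
        from sklearn.metrics import adjusted_rand_score

        truth = TruthLedger.from_json(truth_path)
        summary["ari_vs_truth"] = float(adjusted_rand_score(truth.labels, labels))
    (out_dir / "cluster_summary.json").write_text(json.dumps(summary, indent=1))
    return summary


def stage_hmr(config: PipelineConfig, out_dir: Path) -> dict:
    cohort = _load_cohort(config, out_dir)
    src = _input_dir(config, out_dir)
    islands = io_formats.read_bed(_require(src / "islands.bed", "simulate"))
    genes = exons = None
    if (src / "genes.bed").exists():
        genes = io_formats.read_bed(src / "genes.bed")
    if (src / "exons.bed").exists():
        exons = io_formats.read_bed(src / "exons.bed")
    h = config.hmr
    logger.info("hmr: tau=%.2f max_gap=%d min_cpgs=%d", h.tau, h.max_gap, h.min_cpgs)
    track = regions.build_context_track(islands, cohort.chrom_lengths)
    hmrs = regions.call_hmrs_cohort(
        cohort, tau=h.tau, max_gap=h.max_gap, min_cpgs=h.min_cpgs,
        min_cov=h.min_cov,
    )
    annotated = regions.annotate_hmrs(hmrs, track, genes=genes, exons=exons)
    summary = regions.hmr_summary(annotated)
    io_formats.write_table(annotated, out_dir / "hmrs.tsv")
    io_formats.write_table(summary, out_dir / "hmr_summary.tsv")
    return {"n_hmrs_total": int(len(annotated))}


def stage_cnv(config: PipelineConfig, out_dir: Path) -> dict:
    cohort = _load_cohort(config, out_dir)
    v = config.cnv
    logger.info("cnv: bin_size=%d t_threshold=%.1f", v.bin_size, v.t_threshold)
    segments = regions.call_cnvs(
        cohort, bin_size=v.bin_size, t_threshold=v.t_threshold,
        min_bins=v.min_bins, call_cutoff=v.call_cutoff,
    )
    frac = regions.genome_fraction_cnv(segments, cohort.chrom_lengths)
    io_formats.write_table(segments, out_dir / "cnv_segments.tsv")
    io_formats.write_table(
        frac.rename_axis("sample_id").reset_index(), out_dir / "cnv_summary.tsv"
    )
    return {"n_segments": int(len(segments))}


def _load_expression(config: PipelineConfig, out_dir: Path):
    src = _input_dir(config, out_dir)
    counts, lengths = io_formats.read_counts(_require(src / "counts.tsv", "simulate"))
    return counts, lengths


def stage_de(config: PipelineConfig, out_dir: Path) -> dict:
    counts, lengths = _load_expression(config, out_dir)
    lab = _load_labels(out_dir).set_index("sample_id")["group"]
    labels = lab.reindex(counts.columns).to_numpy()
    tpm_matrix = expression.tpm(counts, lengths)
    io_formats.write_table(
        tpm_matrix.reset_index(), out_dir / "tpm.tsv"
    )
    counts_sig = {}
    for g in sorted(set(labels)):
        de = expression.differential_expression(
            tpm_matrix, labels, g,
            fc_threshold=config.de.fc_threshold,
            p_threshold=config.de.p_threshold,
        )
        volc = expression.volcano_table(de, config.de.fc_threshold,
                                        config.de.p_threshold)
        io_formats.write_table(volc.reset_index(), out_dir / f"de_group{g}.tsv")
        counts_sig[int(g)] = int(de["significant"].sum())
    return {"significant_genes": counts_sig}


def stage_enrich(config: PipelineConfig, out_dir: Path) -> dict:
    src = _input_dir(config, out_dir)
    gmt_path = src / "gene_sets.gmt"
    if not gmt_path.exists():
        gmt_path = Path(__file__).parent / "data" / "markers.gmt"
    gene_sets = io_formats.read_gmt(gmt_path)
    top = {}
    for de_path in sorted(out_dir.glob("de_group*.tsv")):
        g = int(de_path.stem.replace("de_group", ""))
        de = pd.read_csv(de_path, sep="\t")
        universe = set(de["gene_id"])
        query = set(de.loc[de["class"] == "enriched", "gene_id"])
        table = expression.enrich(query, gene_sets, universe)
        io_formats.write_table(table, out_dir / f"enrichment_group{g}.tsv")
        top[g] = table.iloc[0]["set"] if len(table) else None
    if not top:
        raise StageError("de", "no de_group*.tsv tables found; run 'de' first")
    return {"top_set_per_group": top}


def stage_stats(config: PipelineConfig, out_dir: Path) -> dict:
    src = _input_dir(config, out_dir)
    meta = io_formats.read_metadata(_require(src / "metadata.tsv", "simulate"))
    lab = _load_labels(out_dir).set_index("sample_id")["group"]
    meta = meta.set_index("sample_id").loc[lab.index].reset_index()
    labels = lab.to_numpy()
    counts, lengths = _load_expression(config, out_dir)
    tpm_matrix = expression.tpm(counts[lab.index], lengths)
    # group of interest = highest mean mitotic index (the proliferative group)
    means = meta.groupby(labels)["mitotic_index"].mean()
    g_star = int(means.idxmax())
    markers = [m for m in config.synthetic.marker_genes]
    table = cohort_stats.marker_summary(tpm_matrix, meta, labels, markers, g_star)
    grade = cohort_stats.grade_association(meta, labels, g_star)
    table = pd.concat(
        [table, cohort_stats.comparisons_table([grade])], ignore_index=True
    )
    io_formats.write_table(table, out_dir / "comparisons.tsv")
    return {"proliferative_group": g_star,
            "n_comparisons": int(len(table))}


def stage_report(config: PipelineConfig, out_dir: Path) -> dict:
    report: dict = {"seed": config.seed, "stages": {}}
    sections = []
    cs = out_dir / "cluster_summary.json"
    if cs.exists():
        cluster = json.loads(cs.read_text())
        report["stages"]["cluster"] = cluster
        diag = pd.read_csv(out_dir / "k_diagnostics.tsv", sep="\t")
        sections.append("## Group discovery\n\n"
                        f"Selected k = {cluster['k_selected']} "
                        f"(gap k = {cluster['k_gap']}, delta-area k = "
                        f"{cluster['k_delta']}, concordant = "
                        f"{cluster['concordant']})\n\n"
                        + diag.to_markdown(index=False))
        if "ari_vs_truth" in cluster:
            sections.append(f"ARI vs planted labels: {cluster['ari_vs_truth']:.3f}")
    else:
        sections.append("## Group discovery\n\nmissing stage: cluster")
    hs = out_dir / "hmr_summary.tsv"
    if hs.exists():
        summ = pd.read_csv(hs, sep="\t")
        report["stages"]["hmr"] = {"n_hmrs_total": int(summ["n_hmrs"].sum())}
        sections.append("## HMRs\n\n" + summ.to_markdown(index=False))
    else:
        sections.append("## HMRs\n\nmissing stage: hmr")
    cvs = out_dir / "cnv_summary.tsv"
    if cvs.exists():
        summ = pd.read_csv(cvs, sep="\t")
        report["stages"]["cnv"] = {
            "mean_genome_fraction": float(summ["genome_fraction_cnv"].mean())
        }
        sections.append("## CNV\n\n" + summ.to_markdown(index=False))
    else:
        sections.append("## CNV\n\nmissing stage: cnv")
    de_tables = sorted(out_dir.glob("de_group*.tsv"))
    if de_tables:
        counts_sig = {}
        for p in de_tables:
            de = pd.read_csv(p, sep="\t")
            counts_sig[p.stem] = int(de["significant"].sum())
        report["stages"]["de"] = counts_sig
        sections.append("## Differential expression\n\n"
                        + "\n".join(f"- {k}: {v} significant genes"
                                    for k, v in counts_sig.items()))
    else:
        sections.append("## Differential expression\n\nmissing stage: de")
    enr_tables = sorted(out_dir.glob("enrichment_group*.tsv"))
    if enr_tables:
        lines = []
        for p in enr_tables:
            t = pd.read_csv(p, sep="\t")
            if len(t):
                lines.append(f"- {p.stem}: top set {t.iloc[0]['set']} "
                             f"(p = {t.iloc[0]['p']:.3g})")
        report["stages"]["enrich"] = lines
        sections.append("## Enrichment\n\n" + "\n".join(lines))
    else:
        sections.append("## Enrichment\n\nmissing stage: enrich")
    cmp_path = out_dir / "comparisons.tsv"
    if cmp_path.exists():
        cmp_df = pd.read_csv(cmp_path, sep="\t")
        report["stages"]["stats"] = cmp_df.to_dict(orient="records")
        sections.append("## Cohort comparisons\n\n" + cmp_df.to_markdown(index=False))
    else:
        sections.append("## Cohort comparisons\n\nmissing stage: stats")

    (out_dir / "report.json").write_text(json.dumps(report, indent=1, sort_keys=True))
    body = "# methgroup run report\n\n" + "\n\n".join(sections) + "\n"
    (out_dir / "report.md").write_text(body)
    return report


STAGES = {
    "simulate": stage_simulate,
    "cluster": stage_cluster,
    "hmr": stage_hmr,
    "cnv": stage_cnv,
    "de": stage_de,
    "enrich": stage_enrich,
    "stats": stage_stats,
    "report": stage_report,
}


def run(config: PipelineConfig, out_dir: str | Path | None = None) -> dict:
    """Execute every stage in order; partial outputs are preserved on
    failure and the raised :class:`StageError` names the failing stage."""
    out = Path(out_dir if out_dir is not None else config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    config.echo(out)
    order = list(STAGES)
    if config.inputs != "synthetic":
        order.remove("simulate")
    results = {}
    for name in order:
        logger.info("=== stage %s ===", name)
        try:
            results[name] = STAGES[name](config, out)
        except StageError:
            raise
        except Exception as exc:  # noqa: BLE001 - wrap with stage context
            raise StageError(name, str(exc)) from exc
    return results
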