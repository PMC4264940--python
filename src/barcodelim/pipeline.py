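"""End-to-end workflow: distances -> three engines -> consensus -> resolution.

The run writes, under the output directory: per-method partition TSVs, the
ABGD scan table, a GMYC report, the consensus report (TSV + JSON), the
resolution decision log, the final OTU table, the distance histogram, the
OTU accumulation curve and a JSON snapshot of the configuration. Outputs
contain no timestamps, so a fixed config + seed reproduces them
byte-for-byte. A stage failure leaves partial outputs plus a FAILED marker
naming the stage.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path

from . import abgd, consensus, distances, gmyc, resl, resolution, seq_io


@dataclass
class PipelineConfig:
    fasta: str
    metadata: str | None = None
    tree: str | None = None          # optional ultrametric tree for GMYC
    outdir: str = "barcodelim_out"
    # ABGD
    abgd_model: str = "k2p"
    abgd_pmin: float = 0.001
    abgd_pmax: float = 0.1
    abgd_steps: int = 10
    abgd_X: float = 1.5
    abgd_operating_P: float = 0.01   # scan prior nearest this is adopted
    abgd_models_scanned: tuple[str, ...] = ("p", "jc69", "k2p")
    # GMYC
    gmyc_mode: str = "single"        # or "multiple"
    # RESL
    resl_t: float = 0.022
    resl_model: str = "p"
    resl_inflation: float = 2.0
    # misc
    seed: int = 0
    accumulation_permutations: int = 100

    @classmethod
    def from_toml(cls, path: str | Path) -> "PipelineConfig":
        import tomllib
        with open(path, "rb") as fh:
            data = tomllib.load(fh)
        if "abgd_models_scanned" in data:
            data["abgd_models_scanned"] = tuple(data["abgd_models_scanned"])
        return cls(**data)

    def snapshot(self, path: Path) -> None:
        data = dataclasses.asdict(self)
        data["abgd_models_scanned"] = list(self.abgd_models_scanned)
        path.write_text(json.dumps(data, indent=1, sort_keys=True) + "\n")


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline failed at stage {stage!r}: {cause}")
        self.stage = stage
        self.cause = cause


def run_pipeline(config: PipelineConfig) -> Path:
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    failed = outdir / "FAILED"
    if failed.exists():
        failed.unlink()
    config.snapshot(outdir / "config.json")
    stage = "read"
    try:
        alignment = seq_io.read_fasta(config.fasta)
        if config.metadata:
            alignment = seq_io.read_metadata(config.metadata, alignment)

        stage = "distances"
        dms = {m: distances.pairwise_distances(alignment, m)
               for m in config.abgd_models_scanned}
        dm_main = dms.get(config.abgd_model) or distances.pairwise_distances(
            alignment, config.abgd_model)
        hist = distances.distance_histogram(dm_main)
        hist.write_tsv(outdir / "distance_histogram.tsv")

        stage = "abgd"
        params = abgd.AbgdParams(config.abgd_pmin, config.abgd_pmax,
                                 config.abgd_steps, config.abgd_X,
                                 config.abgd_model)
        scan = abgd.abgd_scan(dms, params)
        scan.write_tsv(outdir / "abgd_scan.tsv")
        abgd_part = scan.partition(config.abgd_model, config.abgd_operating_P,
                                   "initial")
        seq_io.write_partition_tsv(abgd_part, outdir / "partition_abgd.tsv")

        stage = "gmyc"
        collapsed, members = seq_io.collapse_haplotypes(alignment)
        if config.tree:
            tree = seq_io.read_tree(config.tree)
            tips = {l.taxon.label for l in tree.leaf_node_iter()}
            if tips == set(alignment.ids):
                # tree already covers every specimen: no expansion needed
                members = {sid: [sid] for sid in alignment.ids}
            elif tips != set(collapsed.ids):
                raise ValueError(
                    "tree tips match neither the specimen set nor the "
                    f"haplotype representatives; unexpected: "
                    f"{sorted(tips ^ set(alignment.ids))[:5]}")
        else:
            dm_hap = distances.pairwise_distances(collapsed, config.abgd_model)
            tree = gmyc.upgma_tree(dm_hap)
        seq_io.write_tree(tree, outdir / "gmyc_input_tree.nwk")
        if config.gmyc_mode == "multiple":
            fit = gmyc.fit_multiple_threshold(tree)
        else:
            fit = gmyc.fit_single_threshold(tree)
        gmyc.write_gmyc_report([fit], outdir / "gmyc_report.tsv")
        gmyc_part = seq_io.expand_partition(fit.partition, members,
                                            alignment.ids)
        seq_io.write_partition_tsv(gmyc_part, outdir / "partition_gmyc.tsv")

        stage = "resl"
        dm_resl = dms.get(config.resl_model) or distances.pairwise_distances(
            alignment, config.resl_model)
        resl_part = resl.resl_partition(
            dm_resl, resl.ReslParams(t=config.resl_t,
                                     inflation=config.resl_inflation))
        seq_io.write_partition_tsv(resl_part, outdir / "partition_resl.tsv")

        stage = "consensus"
        abgd_part.method, gmyc_part.method, resl_part.method = \
            "abgd", "gmyc", "resl"
        report = consensus.build_report([abgd_part, gmyc_part, resl_part])
        report.write_tsv(outdir / "consensus.tsv")
        report.to_json(outdir / "consensus.json")
        report.counts().to_csv(outdir / "category_counts.tsv", sep="\t",
                               index=False)

        stage = "resolve"
        guide = resolution.nj_tree(dm_main)
        seq_io.write_tree(guide, outdir / "guide_tree_nj.nwk")
        final, decisions = resolution.resolve(report, guide, alignment)
        resolution.write_decision_log(decisions, outdir / "decisions.tsv")
        categories = {sid: u.category for u in report.units for sid in u.members}
        seq_io.write_otu_table(
            {"abgd": abgd_part, "gmyc": gmyc_part, "resl": resl_part},
            outdir / "final_otus.tsv", categories=categories,
            final=final.partition)
        counts = final.bookkeeping
        summary = {
            "final_otus": final.n_otus,
            "bookkeeping": counts,
            "final_count_check": resolution.final_count(
                counts["FULL"],
                counts["PARTIAL_SPLIT"] + counts["PARTIAL_MERGED"],
                counts["DISCORDANT"]),
        }
        (outdir / "summary.json").write_text(
            json.dumps(summary, indent=1, sort_keys=True) + "\n")

        stage = "accumulation"
        curve = resolution.otu_accumulation_curve(
            final.partition, config.accumulation_permutations, config.seed)
        curve.to_csv(outdir / "accumulation_curve.tsv", sep="\t", index=False,
                     float_format="%.6g")
    except Exception as exc:
        failed.write_text(f"stage: {stage}\nerror: {exc}\n")
        raise PipelineError(stage, exc) from exc
    return outdir
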