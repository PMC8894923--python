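"""End-to-end orchestration: simulate or load samples, call DMRs, annotate,
profile, analyse restoration, and write a manifest.

Every run is deterministic given the config (including its seed); the run
directory contains the echoed config, a structured log, every BED/TSV
product, and ``manifest.json`` listing each file with the stage that wrote
it.  A ``state.json`` marker records completed stages so a partially failed
run is diagnosable and resumable.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd
import yaml

from . import annotate as ann
from . import io as mio
from . import profiles, simulate, transgen
from .binning import BinGrid, bin_methylation, pool_replicates
from .config import normalize_config, validate_config
from .dmr import DmrParams, call_dmrs, call_ectopic_chg, dmrs_to_frame
from .io import MethylomeTable, ValidationError


class PipelineRun:
    def __init__(self, config: dict, outdir: Path):
        self.config = config
        self.outdir = outdir
        self.manifest: list[dict] = []
        self.log_lines: list[str] = []
        self.state: list[str] = []

    def log(self, stage: str, message: str) -> None:
        self.log_lines.append(f"[{stage}] {message}")

    def record(self, stage: str, path: Path) -> None:
        self.manifest.append({"stage": stage, "path": str(path.relative_to(self.outdir))})

    def write_frame(self, stage: str, df: pd.DataFrame, name: str) -> Path:
        path = self.outdir / name
        df.to_csv(path, sep="\t", index=False)
        self.record(stage, path)
        return path

    def finish_stage(self, stage: str) -> None:
        self.state.append(stage)
        (self.outdir / "state.json").write_text(json.dumps({"completed": self.state}))


def _dmr_params(cfg: dict, context: str, direction: str = "hypo") -> DmrParams:
    p = cfg["params"]
    if direction == "ectopic":
        sub = p["ectopic_CHG"]
        return DmrParams(
            context="CHG",
            direction="ectopic",
            min_dmc=sub["min_dmc"],
            min_diff=sub["min_diff"],
            merge_gap=p["merge_gap"],
            bin_size=p["bin_size"],
            min_cov=p["min_cov"],
            control_max_level=sub.get("control_max_level", 0.02),
        )
    sub = p[context]
    return DmrParams(
        context=context,
        direction=direction,
        min_dmc=sub["min_dmc"],
        min_diff=sub["min_diff"],
        merge_gap=p["merge_gap"],
        bin_size=p["bin_size"],
        min_cov=p["min_cov"],
    )


def _load_samples(cfg: dict, run: PipelineRun):
    """Either simulate the study or read the configured report files."""
    samples: dict[str, MethylomeTable] = {}
    roles: dict[str, str] = {}
    features = None
    if cfg["simulate"] is not None:
        sim_kwargs = dict(cfg["simulate"])
        sim_kwargs.setdefault("seed", cfg["seed"])
        sim_cfg = simulate.SimConfig(**sim_kwargs)
        study = simulate.simulate_study(sim_cfg)
        features = study["features"]
        indir = run.outdir / "inputs"
        indir.mkdir(exist_ok=True)
        mio.write_fasta(study["genome"], indir / "genome.fa")
        run.record("simulate", indir / "genome.fa")
        mio.write_gff3_features(features, indir / "annotation.gff3")
        run.record("simulate", indir / "annotation.gff3")
        for sid, reg in study["registries"].items():
            reg.to_csv(indir / f"registry_{sid}.tsv", sep="\t", index=False)
            run.record("simulate", indir / f"registry_{sid}.tsv")
        for sid, table in study["samples"].items():
            mio.write_cytosine_report(table, indir / f"{sid}.cx.tsv")
            run.record("simulate", indir / f"{sid}.cx.tsv")
            samples[sid] = table
            if sid.startswith("untreated"):
                roles[sid] = "control_untreated"
            elif sid.startswith("solvent"):
                roles[sid] = "control_solvent"
            elif sid.startswith("sibling"):
                roles[sid] = "em3_line"
            else:
                roles[sid] = "treated_line"
        run.log("simulate", f"generated {len(samples)} samples, genome {sim_cfg.chrom_length} bp")
    else:
        for s in cfg["samples"]:
            samples[s["id"]] = mio.read_cytosine_report(
                s["path"], s["id"], genome_id=cfg["genome_id"]
            )
            roles[s["id"]] = s["role"]
        if cfg["annotation"]:
            features = mio.read_gff3_features(cfg["annotation"])
        run.log("load", f"read {len(samples)} cytosine reports")
    return samples, roles, features


def run_pipeline(config: dict | str | Path, outdir: str | Path | None = None) -> Path:
    """Run the full analysis; returns the run directory."""
    if not isinstance(config, dict):
        cfg = validate_config(config)
    else:
        cfg = normalize_config(config)
    out = Path(outdir) if outdir is not None else Path(cfg["output_dir"])
    out.mkdir(parents=True, exist_ok=True)
    run = PipelineRun(cfg, out)
    (out / "config.yaml").write_text(yaml.safe_dump(cfg, sort_keys=True))
    run.record("setup", out / "config.yaml")

    samples, roles, features = _load_samples(cfg, run)
    run.finish_stage("load")

    controls = [samples[sid] for sid, r in roles.items() if r == "control_untreated"]
    if not controls:
        controls = [samples[sid] for sid, r in roles.items() if r == "control_solvent"]
    treated_ids = [sid for sid, r in roles.items() if r == "treated_line"]
    em3_ids = [sid for sid, r in roles.items() if r == "em3_line"]
    if not controls or not treated_ids:
        raise ValidationError("need >=1 control and >=1 treated sample")
    control = pool_replicates(controls, sample_id="control_pooled")
    run.log("pool", f"pooled {len(controls)} control replicates")

    # DMR calling per treated line: CG hypo + ectopic CHG
    all_dmrs: dict[str, list] = {}
    cg_params = _dmr_params(cfg, "CG", "hypo")
    ect_params = _dmr_params(cfg, "CHG", "ectopic")
    for sid in treated_ids:
        dmrs = call_dmrs(control, samples[sid], cg_params)
        all_dmrs[sid] = dmrs
        frame = dmrs_to_frame(dmrs)
        run.write_frame("call_dmrs", frame, f"dmrs_CG_hypo_{sid}.tsv")
        mio.write_dmr_bed(dmrs, out / f"dmrs_CG_hypo_{sid}.bed")
        run.record("call_dmrs", out / f"dmrs_CG_hypo_{sid}.bed")
        ect = call_ectopic_chg(control, samples[sid], ect_params)
        run.write_frame("call_ectopic", dmrs_to_frame(ect), f"dmrs_CHG_ectopic_{sid}.tsv")
        run.log("call_dmrs", f"{sid}: {len(dmrs)} CG hypo DMRs, {len(ect)} ectopic CHG DMRs")
    run.finish_stage("call_dmrs")

    # annotation + DEG intersection
    if features is not None and len(features.df):
        for sid in treated_ids:
            annotated = ann.classify_dmrs(all_dmrs[sid], features)
            run.write_frame("annotate", ann.annotation_to_frame(annotated), f"dmrs_annotated_{sid}.tsv")
            near = ann.genes_near_dmrs(all_dmrs[sid], features, window=cfg["window"])
            mio.write_gene_list(near, out / f"genes_near_dmrs_{sid}.txt")
            run.record("annotate", out / f"genes_near_dmrs_{sid}.txt")
            for deg_path in cfg["deg_lists"]:
                degs = mio.read_gene_list(deg_path)
                inter = ann.intersect_gene_sets(near, degs)
                res = ann.multiset_exact_test([near, degs], universe_size=len(features.genes))
                pd.DataFrame(
                    [
                        {
                            "dmr_sample": sid,
                            "deg_list": degs.label,
                            "n_near": len(near),
                            "n_deg": len(degs),
                            "n_overlap": len(inter),
                            "expected": res.expected,
                            "fold": res.fold,
                            "p_value": res.p_value,
                        }
                    ]
                ).to_csv(out / f"deg_overlap_{sid}.tsv", sep="\t", index=False)
                run.record("annotate", out / f"deg_overlap_{sid}.tsv")
        run.finish_stage("annotate")

    # multi-set overlap of differentially methylated bins across treated lines
    if len(treated_ids) >= 2:
        grid = BinGrid(cfg["params"]["bin_size"])
        bin_sets = []
        defined_keys = None
        for sid in treated_ids:
            bins = bin_methylation(samples[sid], "CG", grid, cfg["params"]["min_cov"])
            keys = set(
                zip(bins.loc[bins["n_covered"] > 0, "chrom"], bins.loc[bins["n_covered"] > 0, "start"])
            )
            defined_keys = keys if defined_keys is None else defined_keys & keys
            member = set()
            for d in all_dmrs[sid]:
                for bs, _be in d.member_bins:
                    member.add((d.chrom, bs))
            bin_sets.append(member)
        bin_sets = [s & defined_keys for s in bin_sets]
        if all(bin_sets) and len(defined_keys) > 0:
            res = ann.multiset_exact_test(bin_sets, universe_size=len(defined_keys))
            pd.DataFrame(
                [
                    {
                        "k": len(bin_sets),
                        "sizes": ",".join(str(s) for s in res.set_sizes),
                        "universe": res.universe_size,
                        "observed": res.observed,
                        "expected": res.expected,
                        "fold": res.fold,
                        "p_value": res.p_value,
                    }
                ]
            ).to_csv(out / "bin_overlap_test.tsv", sep="\t", index=False)
            run.record("overlap_test", out / "bin_overlap_test.tsv")
        run.finish_stage("overlap_test")

    # profiles
    if features is not None and len(features.genes):
        prof = profiles.gene_metaplot(control, features, context="CG")
        run.write_frame("metaplot", prof.df, "metaplot_control_CG.tsv")
    first_treated = samples[treated_ids[0]]
    track = profiles.chromosome_ratio_profile(first_treated, control, context="CG")
    run.write_frame("ratio_track", track, f"ratio_{treated_ids[0]}_vs_control.tsv")
    matrix = profiles.dmr_sample_matrix(
        all_dmrs[treated_ids[0]], list(samples.values()), context="CG"
    )
    matrix.to_csv(out / "dmr_sample_matrix.tsv", sep="\t")
    run.record("matrix", out / "dmr_sample_matrix.tsv")
    run.finish_stage("profiles")

    # transgenerational restoration on eM3 lines
    if em3_ids:
        parent = samples[treated_ids[0]]
        sib_records = []
        for sid in em3_ids:
            records, summary = transgen.classify_restoration(
                all_dmrs[treated_ids[0]], control, parent, samples[sid],
                restore_threshold=cfg["restore_threshold"], min_loss=cfg["min_loss"],
            )
            sib_records.append(records)
            run.write_frame("transgen", transgen.records_to_frame(records), f"restoration_{sid}.tsv")
            run.log("transgen", f"{sid}: restored fraction {summary['restored_fraction']:.3f}")
        if len(sib_records) >= 2:
            joint = transgen.compare_sibling_lines(sib_records[0], sib_records[1])
            run.write_frame("transgen", joint, "sibling_segregation.tsv")
            seg = joint[joint["joint"] == "segregating"]
            with open(out / "segregating_dmrs.bed", "w") as fh:
                for chrom, start, end in seg[["chrom", "start", "end"]].itertuples(index=False):
                    fh.write(f"{chrom}\t{start}\t{end}\tsegregating\t0\t.\n")
            run.record("transgen", out / "segregating_dmrs.bed")
        run.finish_stage("transgen")

    (out / "manifest.json").write_text(json.dumps({"files": run.manifest}, indent=2))
    (out / "run.log").write_text("\n".join(run.log_lines) + "\n")
    return out
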