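"""End-to-end pipeline: simulate -> preprocess -> cluster -> proliferation ->
concordance -> ggm -> regulators -> pathways, driven by one YAML config.

Stages communicate only via files under the output directory, so each can
be re-run independently; a manifest records the config hash, package
version, per-stage outputs and every derived RNG stream.  Re-running with
an identical config and seed reproduces the output directory byte for
byte.
"""

from __future__ import annotations

import hashlib
import json
from importlib.metadata import version as pkg_version
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, Field, model_validator

from . import concordance as conc
from . import consensus as cons
from . import ggm as ggm_mod
from . import preprocess as prep
from . import proliferation as prolif
from . import regulators as regs
from . import simulate as sim
from .screens import (
    read_discrete,
    read_gmt,
    read_screen,
    write_discrete,
    write_gmt,
    write_network,
    write_screen,
)

__all__ = ["PipelineConfig", "run_all", "load_config", "STAGES"]


class SimulateSection(BaseModel):
    n_mirna: int = 879
    n_protein: int = 127
    cluster_sizes: tuple[int, ...] = (79, 153, 115, 150)
    signature_size: int = 6
    effect_size: float = 1.0
    noise_sd: float = 0.25
    n_controls: int = 8
    n_mirna_subset: int = 154
    shared_proteins: int = 103
    flip_prob: float = Field(0.0, ge=0.0, le=1.0)
    partial_corr_magnitude: float = 0.35
    ggm_p: int = 20
    beta: float = 0.12
    prolif_noise_sd: float = 0.02


class PreprocessSection(BaseModel):
    z_threshold: float = Field(1.5, gt=0)
    center: bool = True


class ClusterSection(BaseModel):
    k_min: int = Field(2, ge=2)
    k_max: int = 15
    n_resamples: int = Field(100, ge=1)
    holdout_frac: float = Field(0.10, ge=0.0, lt=1.0)
    delta_min: float = 0.025
    n_trees: int = 500
    n_permutations: int = 10

    @model_validator(mode="after")
    def _check_k_order(self):
        if self.k_max < self.k_min:
            raise ValueError(
                f"k_max ({self.k_max}) must be >= k_min ({self.k_min})"
            )
        return self


class ProliferationSection(BaseModel):
    high_threshold: float = 0.05
    low_quantile: float = Field(0.10, gt=0.0, lt=1.0)
    r_threshold: float = Field(0.3, ge=0.0)
    no_change_band: float = 0.01
    svm_C: float = Field(1.0, gt=0)


class GGMSection(BaseModel):
    lambda_min: float = Field(0.01, gt=0)
    n_lambda: int = Field(20, ge=1)
    ebic_gamma: float = 0.5


class RegulatorSection(BaseModel):
    min_lines: int = Field(2, ge=1)
    min_targets: int = Field(2, ge=1)
    pathway_threshold: float = Field(0.5, ge=0.0, le=1.0)


class PipelineConfig(BaseModel):
    seed: int = 0
    simulate: SimulateSection = SimulateSection()
    preprocess: PreprocessSection = PreprocessSection()
    cluster: ClusterSection = ClusterSection()
    proliferation: ProliferationSection = ProliferationSection()
    ggm: GGMSection = GGMSection()
    regulators: RegulatorSection = RegulatorSection()

    def sim_config(self) -> sim.SimulationConfig:
        s = self.simulate
        return sim.SimulationConfig(
            n_mirna=s.n_mirna, n_protein=s.n_protein,
            cluster_sizes=s.cluster_sizes, signature_size=s.signature_size,
            effect_size=s.effect_size, noise_sd=s.noise_sd,
            n_controls=s.n_controls, seed=self.seed,
        )


def load_config(path: str | Path) -> PipelineConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    return PipelineConfig.model_validate(data)


def _config_hash(config: PipelineConfig) -> str:
    canonical = json.dumps(config.model_dump(), sort_keys=True, default=list)
    return hashlib.sha256(canonical.encode()).hexdigest()


CELL_LINE_ORDER = ("A", "B", "C")


def _write_labels(path: Path, mirna_ids, labels) -> None:
    pd.DataFrame({"mirna": mirna_ids, "cluster": labels}).to_csv(
        path, sep="\t", index=False
    )


# ---------------------------------------------------------------------------
# Stages
# ---------------------------------------------------------------------------

def stage_simulate(config: PipelineConfig, out: Path) -> list[str]:
    sc = config.sim_config()
    d = out / "screens"
    d.mkdir(parents=True, exist_ok=True)
    primary, labels = sim.simulate_primary_screen(sc)
    write_screen(primary, d / "screen1_raw.tsv")
    _write_labels(d / "truth_labels.tsv", primary.mirna_ids, labels)
    ggms, classes = sim.planted_cell_line_ggms(
        p=config.simulate.ggm_p,
        partial_corr_magnitude=config.simulate.partial_corr_magnitude,
        seed=config.seed,
    )
    second = sim.simulate_secondary_screens(
        sc, ggms, n_mirna_subset=config.simulate.n_mirna_subset,
        shared_proteins=config.simulate.shared_proteins,
        flip_prob=config.simulate.flip_prob, seed=config.seed,
    )
    files = ["screens/screen1_raw.tsv", "screens/truth_labels.tsv"]
    for s in second.screens:
        write_screen(s, d / f"screen2_{s.cell_line}.tsv")
        files.append(f"screens/screen2_{s.cell_line}.tsv")
    for line, g in sorted(ggms.items()):
        pd.DataFrame(g.precision, index=g.proteins, columns=g.proteins).to_csv(
            d / f"planted_precision_{line}.tsv", sep="\t", float_format="%.10g"
        )
        files.append(f"screens/planted_precision_{line}.tsv")
    second.regulators.to_csv(d / "planted_regulators.tsv", sep="\t", index=False)
    write_gmt(sim.default_pathways(), d / "pathways.gmt")
    with open(d / "config_snapshot.yaml", "w") as fh:
        yaml.safe_dump(config.model_dump(), fh, sort_keys=True, default_flow_style=False)
    # proliferation read-out belongs to the simulated study design
    no_ctrl = primary.subset(
        mirnas=[m for m in primary.mirna_ids if not m.startswith("NTC-")]
    )
    table = sim.simulate_proliferation(
        no_ctrl, beta=config.simulate.beta,
        noise_sd=config.simulate.prolif_noise_sd, seed=config.seed,
    )
    table.to_frame().to_csv(d / "proliferation_raw.tsv", sep="\t", float_format="%.10g")
    files += ["screens/planted_regulators.tsv", "screens/pathways.gmt",
              "screens/config_snapshot.yaml", "screens/proliferation_raw.tsv"]
    return files


def stage_preprocess(config: PipelineConfig, out: Path) -> list[str]:
    d = out / "screens"
    raw = read_screen(d / "screen1_raw.tsv", cell_line="A", screen_id="screen1")
    controls = [m for m in raw.mirna_ids if m.startswith("NTC-")]
    norm = prep.normalize(raw, controls, center=config.preprocess.center,
                          drop_controls=True)
    write_screen(norm, d / "screen1_norm.tsv")
    disc = prep.discretize(norm, config.preprocess.z_threshold)
    write_discrete(disc, d / "screen1_disc.tsv")
    files = ["screens/screen1_norm.tsv", "screens/screen1_disc.tsv"]
    for line in CELL_LINE_ORDER:
        p = d / f"screen2_{line}.tsv"
        if not p.exists():
            continue
        s2 = read_screen(p, cell_line=line, screen_id="screen2")
        disc2 = prep.discretize(s2, config.preprocess.z_threshold)
        write_discrete(disc2, d / f"screen2_{line}_disc.tsv")
        files.append(f"screens/screen2_{line}_disc.tsv")
    return files


def stage_cluster(config: PipelineConfig, out: Path) -> list[str]:
    d = out / "clustering"
    d.mkdir(exist_ok=True)
    screen = read_screen(out / "screens" / "screen1_norm.tsv")
    cc = config.cluster
    result = cons.consensus_cluster(
        screen, range(cc.k_min, cc.k_max + 1), n_resamples=cc.n_resamples,
        holdout_frac=cc.holdout_frac, delta_min=cc.delta_min, seed=config.seed,
    )
    _write_labels(d / "labels.tsv", screen.mirna_ids, result.labels)
    pd.DataFrame({
        "k": result.k_range,
        "area": [result.area[k] for k in result.k_range],
        "delta_area": [result.delta_area[k] for k in result.k_range],
        "undefined_pairs": [result.undefined_pairs[k] for k in result.k_range],
    }).to_csv(d / "delta_area.tsv", sep="\t", index=False, float_format="%.10g")
    with open(d / "selected_k.json", "w") as fh:
        json.dump({"selected_k": int(result.selected_k)}, fh, sort_keys=True)
        fh.write("\n")
    markers = cons.rank_markers(
        screen, result.labels, n_trees=cc.n_trees,
        n_permutations=cc.n_permutations, seed=config.seed,
    )
    rows = []
    for cid in sorted(markers.rankings):
        for rank, (protein, score) in enumerate(markers.rankings[cid], start=1):
            rows.append({"cluster": cid, "rank": rank, "protein": protein,
                         "importance": score})
    pd.DataFrame(rows).to_csv(d / "markers.tsv", sep="\t", index=False,
                              float_format="%.10g")
    return ["clustering/labels.tsv", "clustering/delta_area.tsv",
            "clustering/selected_k.json", "clustering/markers.tsv"]


def stage_proliferation(config: PipelineConfig, out: Path) -> list[str]:
    d = out / "proliferation"
    d.mkdir(exist_ok=True)
    screen = read_screen(out / "screens" / "screen1_norm.tsv")
    raw = pd.read_csv(out / "screens" / "proliferation_raw.tsv", sep="\t",
                      index_col=0)
    from .screens import ProliferationTable
    table = ProliferationTable(list(raw.index), raw["rel_change"].to_numpy())
    pc = config.proliferation
    binned = prolif.bin_proliferation(table, pc.high_threshold, pc.low_quantile)
    binned.to_frame().to_csv(d / "groups.tsv", sep="\t", float_format="%.10g")
    report = prolif.correlate_proliferation(screen, binned, pc.r_threshold)
    report.table.to_csv(d / "correlation.tsv", sep="\t", float_format="%.10g")
    svm = prolif.svm_loocv(screen, binned, C=pc.svm_C)
    pd.DataFrame(svm.confusion, index=["pred_low", "pred_high"],
                 columns=["true_low", "true_high"]).to_csv(
        d / "confusion.tsv", sep="\t")
    summary = {
        "loocv_accuracy": svm.loocv_accuracy,
        "n_grouped": svm.n_total,
        "n_low": int((binned.group == "low").sum()),
        "n_high": int((binned.group == "high").sum()),
        "no_change_fraction": prolif.no_change_fraction(binned, pc.no_change_band),
    }
    with open(d / "summary.json", "w") as fh:
        json.dump(summary, fh, sort_keys=True, indent=1)
        fh.write("\n")
    return ["proliferation/groups.tsv", "proliferation/correlation.tsv",
            "proliferation/confusion.tsv", "proliferation/summary.json"]


def stage_concordance(config: PipelineConfig, out: Path) -> list[str]:
    d = out / "concordance"
    d.mkdir(exist_ok=True)
    a = read_discrete(out / "screens" / "screen1_disc.tsv")
    b = read_discrete(out / "screens" / "screen2_A_disc.tsv")
    tm = conc.transition_matrix(a, b)
    tm.to_frame().to_csv(d / "transitions.tsv", sep="\t")
    per = conc.per_mirna_consistency(a, b)
    per.to_csv(d / "per_mirna.tsv", sep="\t", float_format="%.10g")
    summary = {
        "n_pairs": tm.n_pairs,
        "overlap": tm.overlap,
        "overlap_reverse": tm.overlap_reverse,
        "per_mirna_mean_overlap": (
            None if per["overlap"].dropna().empty
            else float(per["overlap"].dropna().mean())
        ),
    }
    with open(d / "summary.json", "w") as fh:
        json.dump(summary, fh, sort_keys=True, indent=1)
        fh.write("\n")
    return ["concordance/transitions.tsv", "concordance/per_mirna.tsv",
            "concordance/summary.json"]


def stage_ggm(config: PipelineConfig, out: Path) -> list[str]:
    d = out / "networks"
    d.mkdir(exist_ok=True)
    files = []
    nets = []
    for line in CELL_LINE_ORDER:
        screen = read_screen(out / "screens" / f"screen2_{line}.tsv",
                             cell_line=line)
        net = ggm_mod.infer_network(
            screen, gamma=config.ggm.ebic_gamma,
            lambda_min=config.ggm.lambda_min, n_lambda=config.ggm.n_lambda,
        )
        nets.append(net)
        net.edges.to_csv(d / f"ggm_{line}_edges.tsv", sep="\t", index=False,
                         float_format="%.10g")
        write_network(net.to_edge_table(), d / f"ggm_{line}.graphml", "graphml")
        files += [f"networks/ggm_{line}_edges.tsv", f"networks/ggm_{line}.graphml"]
    comp = ggm_mod.compare_networks(nets)
    counts = {"&".join(k): v for k, v in comp.region_counts.items()}
    with open(d / "comparison.json", "w") as fh:
        json.dump({"region_counts": counts,
                   "common_core": ["|".join(e) for e in comp.common_core]},
                  fh, sort_keys=True, indent=1)
        fh.write("\n")
    comp.to_frame().to_csv(d / "hive_edges.tsv", sep="\t", index=False)
    return files + ["networks/comparison.json", "networks/hive_edges.tsv"]


def stage_regulators(config: PipelineConfig, out: Path) -> list[str]:
    d = out / "networks"
    d.mkdir(exist_ok=True)
    screens = [read_discrete(out / "screens" / f"screen2_{line}_disc.tsv",
                             cell_line=line)
               for line in CELL_LINE_ORDER]
    from .screens import is_phospho
    phospho = [p for p in screens[0].protein_ids if is_phospho(p)]
    labels_df = pd.read_csv(out / "clustering" / "labels.tsv", sep="\t")
    clusters = dict(zip(labels_df["mirna"], labels_df["cluster"]))
    rc = config.regulators
    up, down = regs.build_phospho_regulators(
        screens, phospho, min_lines=rc.min_lines, min_targets=rc.min_targets,
        cluster_labels=clusters,
    )
    files = []
    for name, net in (("up", up), ("down", down)):
        net.edges.to_csv(d / f"regulators_{name}.tsv", sep="\t", index=False)
        write_network(net.to_edge_table(), d / f"regulators_{name}.graphml",
                      "graphml")
        files += [f"networks/regulators_{name}.tsv",
                  f"networks/regulators_{name}.graphml"]
    return files


def stage_pathways(config: PipelineConfig, out: Path) -> list[str]:
    d = out / "pathways"
    d.mkdir(exist_ok=True)
    disc = read_discrete(out / "screens" / "screen1_disc.tsv")
    pathways = read_gmt(out / "screens" / "pathways.gmt")
    labels_df = pd.read_csv(out / "clustering" / "labels.tsv", sep="\t")
    clusters = dict(zip(labels_df["mirna"], labels_df["cluster"]))
    reg = regs.pathway_fractions(disc, pathways,
                                 threshold=config.regulators.pathway_threshold)
    reg.table.to_csv(d / "pathway_fractions.tsv", sep="\t", index=False,
                     float_format="%.10g")
    g = regs.export_pathway_network(reg, clusters)
    import networkx as nx
    nx.write_graphml(g, d / "pathway_network.graphml")
    return ["pathways/pathway_fractions.tsv", "pathways/pathway_network.graphml"]


STAGES = (
    ("simulate", stage_simulate),
    ("preprocess", stage_preprocess),
    ("cluster", stage_cluster),
    ("proliferation", stage_proliferation),
    ("concordance", stage_concordance),
    ("ggm", stage_ggm),
    ("regulators", stage_regulators),
    ("pathways", stage_pathways),
)


def run_all(config: PipelineConfig | str | Path, outdir: str | Path) -> Path:
    """Run every stage in order and write the run manifest.

    Any stage failure aborts with the stage name in the error message.
    """
    if not isinstance(config, PipelineConfig):
        config = load_config(config)
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "package": "mirscreen",
        "version": pkg_version("mirscreen"),
        "seed": config.seed,
        "config_sha256": _config_hash(config),
        "rng_streams": {
            "simulate": f"SeedSequence({config.seed}, spawn_key=(0|1|2|3,...))",
            "proliferation": f"SeedSequence({config.seed}, spawn_key=(10,))",
            "planted_ggms": f"SeedSequence({config.seed}, spawn_key=(20|21,))",
            "cluster": f"SeedSequence({config.seed}, spawn_key=(k, resample))",
            "markers": f"SeedSequence({config.seed}, spawn_key=(40, cluster))",
        },
        "stages": {},
    }
    for name, fn in STAGES:
        try:
            manifest["stages"][name] = fn(config, out)
        except Exception as exc:
            raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc
    # manifest itself is the ninth output
    manifest["stages"]["manifest"] = ["manifest.json"]
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, sort_keys=True, indent=1)
        fh.write("\n")
    return out
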