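"""End-to-end orchestration: simulate → normalize → debarcode → gate →
featurize → test → report.

The run is a pure function of its configuration: the same ``RunConfig``
(including its seed) produces byte-identical result tables.  Intermediate
per-stage event accounting is collected in a manifest whose conservation
check (events in = assigned + unassigned + beads) is asserted on every run.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import features as feat
from . import stats as st
from .gating import GateTree, apply_gates, default_gate_tree
from .preprocess import (apply_normalization, debarcode, fit_normalization,
                         identify_beads, pooled_bead_reference)
from .synthetic import (EventMatrix, ExperimentTruth, TruthConfig, cbc_table,
                        experiment_metas, make_truth, outcome_table,
                        simulate_batch)


@dataclass
class RunConfig:
    seed: int = 0
    n_animals_per_group: int = 8
    n_events_per_sample: int = 5000
    bead_fraction: float = 0.03
    doublet_rate: float = 0.01
    batch_size: int = 16
    separation_cutoff: float = 0.3
    max_mahalanobis: float = 30.0       # squared-distance convention
    normalization_window: int = 500
    gate_cutoff: float = 2.2
    min_cells: int = 20
    volcano_p_cutoff: float = 0.05
    volcano_diff_cutoff: float = 0.1
    top_fraction: float = 0.2
    write_plots: bool = False

    def validate(self) -> None:
        if not 0 <= self.bead_fraction <= 0.2:
            raise ValueError("bead_fraction outside [0, 0.2]")
        if not 0 < self.top_fraction <= 1:
            raise ValueError("top_fraction outside (0, 1]")
        if self.separation_cutoff < 0 or self.max_mahalanobis <= 0:
            raise ValueError("thresholds out of range")
        if self.n_events_per_sample < 1 or self.n_animals_per_group < 1:
            raise ValueError("sizes must be positive")

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls(**yaml.safe_load(fh))

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]


@dataclass
class RunManifest:
    config_hash: str
    stages: dict = field(default_factory=dict)
    checksums: dict = field(default_factory=dict)
    warnings: list = field(default_factory=list)

    def check_conservation(self) -> None:
        s = self.stages
        total = s.get("events_simulated", 0)
        acc = (s.get("beads_removed", 0) + s.get("events_assigned", 0)
               + s.get("events_unassigned", 0))
        if total != acc:
            raise AssertionError(
                f"event conservation violated: {total} simulated != "
                f"{acc} accounted")


@dataclass
class PipelineResult:
    truth: ExperimentTruth
    tree: GateTree
    frequencies: pd.DataFrame
    pseudo_counts: pd.DataFrame
    responses: pd.DataFrame
    group_tests: pd.DataFrame
    volcano: pd.DataFrame
    top_features: pd.DataFrame
    anova: pd.DataFrame
    zscores: pd.DataFrame
    log2_ratios: pd.DataFrame
    outcome_correlations: pd.DataFrame
    yield_report: pd.DataFrame
    manifest: RunManifest


def _truth_config(config: RunConfig) -> TruthConfig:
    tc = TruthConfig()
    tc.groups = {g: config.n_animals_per_group for g in tc.groups}
    return tc


def run_pipeline(config: RunConfig | None = None,
                 truth_config: TruthConfig | None = None,
                 tree: GateTree | None = None) -> PipelineResult:
    """Run the full analysis on one synthetic experiment."""
    config = config or RunConfig()
    config.validate()
    truth = make_truth(truth_config or _truth_config(config), config.seed)
    tree = tree or default_gate_tree(config.gate_cutoff)
    manifest = RunManifest(config_hash=config.config_hash())

    batches = experiment_metas(truth, config.batch_size)
    meta_by_sample = {m.sample_id: m for batch in batches for m in batch}

    # ---- simulate + identify beads, per batch ---------------------------
    sim = []
    for batch in batches:
        ev, scheme = simulate_batch(
            truth, batch, config.n_events_per_sample, config.bead_fraction,
            config.doublet_rate)
        bead_mask = identify_beads(ev)
        beads = EventMatrix(ev.data[bead_mask].reset_index(drop=True),
                            ev.panel)
        cells = EventMatrix(
            ev.data[~bead_mask].reset_index(drop=True), ev.panel,
            ev.truth[~bead_mask].reset_index(drop=True)
            if ev.truth is not None else None)
        sim.append((cells, beads, scheme))
    manifest.stages["events_simulated"] = sum(
        c.n_events + b.n_events for c, b, _ in sim)
    manifest.stages["beads_removed"] = sum(b.n_events for _, b, _ in sim)

    # ---- normalize across batches + debarcode ---------------------------
    reference = pooled_bead_reference([b for _, b, _ in sim])
    per_sample: dict[str, EventMatrix] = {}
    yields = []
    n_assigned = n_unassigned = 0
    for i, (cells, beads, scheme) in enumerate(sim):
        if beads.n_events:
            # small runs may hold fewer beads than one full window; a single
            # clamped window then gives one constant correction per channel
            window = min(config.normalization_window, beads.n_events)
            factors = fit_normalization(beads, window, reference=reference)
            cells = apply_normalization(cells, factors)
        else:
            manifest.warnings.append(
                f"batch{i + 1}: no bead events; normalization skipped")
        dres = debarcode(cells, scheme, config.separation_cutoff,
                         config.max_mahalanobis)
        rep = dres.yield_report.copy()
        rep["batch"] = f"batch{i + 1}"
        yields.append(rep)
        assigned = rep.loc[rep["status"] == "assigned", "count"].sum()
        n_assigned += int(assigned)
        n_unassigned += int(cells.n_events - assigned)
        per_sample.update(dres.samples)
    manifest.stages["events_assigned"] = n_assigned
    manifest.stages["events_unassigned"] = n_unassigned
    manifest.check_conservation()
    yield_report = pd.concat(yields, ignore_index=True)

    # ---- gate + featurize ------------------------------------------------
    counts, gated = [], []
    for sid, ev in per_sample.items():
        meta = meta_by_sample[sid]
        gr = apply_gates(ev, tree)
        counts.append((meta, gr.counts))
        gated.append((meta, ev, gr))
    frequencies = feat.compute_frequencies(counts)
    cbc = cbc_table(truth)
    pseudo = feat.pseudo_absolute_counts(frequencies, cbc)
    medians = feat.signaling_medians(gated, min_cells=config.min_cells)
    responses = feat.stim_response(medians)

    # ---- statistics ------------------------------------------------------
    group_tests = st.group_vs_mock_tests(frequencies)
    volcano = st.stim_response_tests(
        responses, config.volcano_p_cutoff, config.volcano_diff_cutoff)
    top = st.select_top_features(volcano, config.top_fraction)
    anova = st.anova_group_differences(responses, top)
    zscores = st.zscore_table(responses, top)
    log2r = st.log2_ratio_table(frequencies)

    outcomes = outcome_table(truth)
    freq_feats = frequencies[frequencies["stim"] == "UNSTIM"].copy()
    freq_feats["feature_id"] = ("freq|" + freq_feats["tissue"] + "|"
                                + freq_feats["population"])
    freq_feats["family"] = "frequency"
    freq_feats = freq_feats.rename(columns={"frequency": "value"})
    # correlate every response feature, not only the heatmap selection: the
    # BH family (tissue, outcome, family) absorbs the larger feature count
    sig_feats = responses.dropna(subset=["response"]).copy()
    sig_feats["feature_id"] = ("sig|" + sig_feats["tissue"] + "|"
                               + sig_feats["stim"] + "|"
                               + sig_feats["population"] + "|"
                               + sig_feats["marker"])
    sig_feats["family"] = "signaling"
    sig_feats = sig_feats.rename(columns={"response": "value"})
    cols = ["feature_id", "tissue", "family", "animal_id", "group", "value"]
    all_feats = pd.concat([freq_feats[cols], sig_feats[cols]],
                          ignore_index=True)
    correlations = st.correlate_outcomes(all_feats, outcomes)

    return PipelineResult(
        truth=truth, tree=tree, frequencies=frequencies,
        pseudo_counts=pseudo, responses=responses, group_tests=group_tests,
        volcano=volcano, top_features=top, anova=anova, zscores=zscores,
        log2_ratios=log2r, outcome_correlations=correlations,
        yield_report=yield_report, manifest=manifest)


_TABLES = ("frequencies", "pseudo_counts", "responses", "group_tests",
           "volcano", "top_features", "anova", "zscores", "log2_ratios",
           "outcome_correlations", "yield_report")


def report(result: PipelineResult, outdir, plots: bool = False) -> dict:
    """Write all result tables as CSV (and optional simple plots).

    Returns the manifest dict, including sha256 checksums of every file.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for name in _TABLES:
        df: pd.DataFrame = getattr(result, name)
        path = outdir / f"{name}.csv"
        df.to_csv(path, index=False)
        result.manifest.checksums[path.name] = hashlib.sha256(
            path.read_bytes()).hexdigest()
    if plots:
        _write_plots(result, outdir)
    manifest = {
        "config_hash": result.manifest.config_hash,
        "stages": result.manifest.stages,
        "checksums": result.manifest.checksums,
        "warnings": result.manifest.warnings,
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest


def _write_plots(result: PipelineResult, outdir: Path) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    v = result.volcano
    if len(v):
        fig, ax = plt.subplots(figsize=(5, 4))
        colors = v["direction"].map(
            {"up": "red", "down": "blue", "ns": "grey"})
        ax.scatter(v["mean_change"], -np.log10(v["p_raw"].clip(lower=1e-30)),
                   c=colors, s=8)
        ax.set_xlabel("mean arcsinh change")
        ax.set_ylabel("-log10 p (uncorrected)")
        fig.savefig(outdir / "volcano.png", dpi=100)
        plt.close(fig)
    z = result.zscores
    if len(z):
        piv = z.pivot_table(index="feature_id", columns="group",
                            values="zscore")
        fig, ax = plt.subplots(figsize=(5, max(2, 0.3 * len(piv))))
        im = ax.imshow(piv.to_numpy(), aspect="auto", cmap="RdBu_r")
        ax.set_xticks(range(len(piv.columns)), piv.columns)
        ax.set_yticks(range(len(piv.index)), piv.index, fontsize=6)
        fig.colorbar(im, ax=ax, label="Z")
        fig.tight_layout()
        fig.savefig(outdir / "zscore_heatmap.png", dpi=100)
        plt.close(fig)
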