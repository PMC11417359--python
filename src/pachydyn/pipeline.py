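"""End-to-end orchestration: simulate -> QC -> fit -> trend -> binding.

``run_pipeline`` executes every stage on a synthetic two-sample dataset
(or on matrices loaded from disk via the io module), writes each stage's
table under a run directory and returns a machine-readable report whose
counts are re-derivable from the files on disk.  Every stochastic stage
consumes a sub-seed derived deterministically from the master seed, so
a rerun with the same config reproduces byte-identical outputs.
"""

from __future__ import annotations

import json
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import binding, expression, io, kinetics, trend
from .simulate import (
    ARREST_CLUSTER,
    KineticGene,
    MotifSpec,
    SimulationConfig,
    default_gene_panel,
    simulate_dataset,
    simulate_genome,
)

__all__ = ["RunConfig", "RunReport", "analyze_pair", "validate_config", "run_pipeline"]


@dataclass
class RunConfig:
    """All knobs of an end-to-end run, with the study defaults."""

    sim: SimulationConfig = field(default_factory=SimulationConfig)
    qc: expression.QCThresholds = field(default_factory=expression.QCThresholds)
    panel: dict = field(
        default_factory=lambda: {"n_repression": 80, "n_induction": 60, "n_steady": 60}
    )
    genes: list | None = None  # optional explicit gene dicts
    bound_per_class: dict = field(
        default_factory=lambda: {"repression": 30, "induction": 10, "steady": 10}
    )
    n_neighbors: int = 30
    n_pcs: int = 30
    likelihood_threshold: float = 0.0
    time_quantile: float = 0.5
    velocity_quantile: float = 0.7  # velocity field uses the top fits only
    alpha: float = 0.01
    ratio_threshold: float = 4.0
    gate: str = "wt"
    trend_change: str = "sign"
    promoter_upstream: int = 2000
    fit_max_iter: int = 30
    seed: int = 0


@dataclass
class RunReport:
    stage_counts: dict
    driver_count: int
    dgt_count: int
    classification: pd.DataFrame
    category_fractions: pd.Series
    deg_overlap: pd.DataFrame
    terminal_cluster: str
    terminal_scores: dict
    config_fingerprint: str


def _subseed(master: int, k: int) -> int:
    return int(np.random.SeedSequence([master, k]).generate_state(1)[0] % (2**31))


def validate_config(config: RunConfig) -> list[str]:
    """Every embedded invariant checked; returns actionable violations."""
    violations: list[str] = []
    try:
        SimulationConfig(**asdict(config.sim))
    except (ValueError, TypeError) as exc:
        violations.append(f"sim: {exc}")
    try:
        expression.QCThresholds(**asdict(config.qc))
    except (ValueError, TypeError) as exc:
        violations.append(f"qc: {exc}")
    if not 0.0 < config.alpha < 1.0:
        violations.append(f"alpha must lie in (0, 1), got {config.alpha}")
    if config.ratio_threshold <= 0:
        violations.append("ratio_threshold must be positive")
    if config.gate not in ("wt", "ko", "both"):
        violations.append(f"unknown gate {config.gate!r}")
    if config.n_neighbors < 1:
        violations.append("n_neighbors must be >= 1")
    if not 0.0 <= config.likelihood_threshold:
        violations.append("likelihood_threshold must be >= 0")
    for key, v in config.panel.items():
        if v < 0:
            violations.append(f"panel {key} must be >= 0")
    if config.genes is not None:
        for g in config.genes:
            try:
                KineticGene(**g) if isinstance(g, dict) else g
            except (ValueError, TypeError) as exc:
                name = g.get("gene_id", "?") if isinstance(g, dict) else getattr(g, "gene_id", "?")
                violations.append(f"gene {name}: {exc}")
    return violations


def _build_genes(config: RunConfig) -> list[KineticGene]:
    if config.genes is not None:
        return [KineticGene(**g) if isinstance(g, dict) else g for g in config.genes]
    return default_gene_panel(
        config.panel.get("n_repression", 80),
        config.panel.get("n_induction", 60),
        config.panel.get("n_steady", 60),
        seed=_subseed(config.seed, 1),
    )


def _bound_gene_ids(genes: list[KineticGene], per_class: dict, seed: int) -> list[str]:
    rng = np.random.default_rng(seed)
    chosen: list[str] = []
    for cls, k in per_class.items():
        ids = [g.gene_id for g in genes if g.gene_class == cls]
        k = min(k, len(ids))
        chosen.extend(rng.choice(ids, size=k, replace=False))
    return sorted(chosen)


def analyze_pair(pair, config: RunConfig, log: "_StageLogger | None" = None) -> dict:
    """QC, per-sample kinetic fits, drivers, trend calls, terminal states.

    Runs every expression-level stage on an existing two-sample dataset
    and returns the intermediate objects keyed by stage ('per_sample',
    'drivers', 'calls', 'terminal', 'cluster_graph', 'pair_qc').
    """
    log = log or _StageLogger()

    log.start("qc")
    keep = expression.qc_filter(pair.cell_meta, config.qc)
    pair_qc = pair.subset_cells(keep)
    log.done(f"{int(keep.sum())}/{pair.n_cells} cells survive")

    per_sample: dict[str, dict] = {}
    for sample in ("WT", "KO"):
        log.start(f"fit[{sample}]")
        sub = pair_qc.sample(sample)
        n_nb = min(config.n_neighbors, sub.n_cells - 1)
        moments = kinetics.compute_moments(sub, n_neighbors=n_nb, n_pcs=config.n_pcs)
        fits = kinetics.fit_all_genes(moments, max_iter=config.fit_max_iter)
        cell_time = kinetics.inferred_cell_time(fits, config.time_quantile)
        per_sample[sample] = {
            "pair": sub,
            "moments": moments,
            "fits": fits,
            "cell_time": cell_time,
        }
        log.done(f"{sum(f.valid for f in fits)} valid fits / {len(fits)} genes")

    log.start("drivers")
    wt = per_sample["WT"]
    ko = per_sample["KO"]
    drivers = kinetics.select_driver_genes(
        wt["fits"], wt["moments"], threshold=config.likelihood_threshold,
        cell_time=wt["cell_time"],
    )
    log.done(f"{len(drivers)} driver genes")

    log.start("terminal_states")
    # genes without resolvable dynamics only add noise to the field, so
    # the velocity graph uses the best-explained fits
    liks = [f.fit_likelihood for f in ko["fits"] if f.valid]
    cut = float(np.quantile(liks, config.velocity_quantile)) if liks else 0.0
    vfits = [f for f in ko["fits"] if f.valid and f.fit_likelihood >= cut]
    vel = kinetics.compute_velocity(vfits, ko["moments"])
    T = kinetics.velocity_graph(ko["moments"], vel)
    clusters_ko = ko["pair"].cell_meta["cluster"].to_numpy()
    terminal = kinetics.terminal_states(T, clusters_ko)
    cgraph = kinetics.cluster_graph(ko["moments"].knn_indices, clusters_ko, T)
    log.done(f"terminal cluster {terminal.cluster_score.idxmax()}")

    log.start("trend")
    # the trend test runs on raw per-cell unspliced counts: smoothed
    # series are autocorrelated, which makes the Mann-Kendall p-values
    # anti-conservative on flat genes, and library-size normalization
    # imprints composition trends; raw counts have independent errors
    order_wt = np.argsort(wt["cell_time"], kind="stable")
    order_ko = np.argsort(ko["cell_time"], kind="stable")
    gcol = {g: j for j, g in enumerate(wt["moments"].gene_ids)}
    U_wt = np.asarray(wt["pair"].unspliced, dtype=float)
    U_ko = np.asarray(ko["pair"].unspliced, dtype=float)
    calls = []
    for row in drivers.itertuples():
        j = gcol[row.gene_id]
        call = trend.classify_trend(
            row.gene_id,
            U_wt[order_wt, j],
            U_ko[order_ko, j],
            direction=row.direction,
            alpha=config.alpha,
            ratio_threshold=config.ratio_threshold,
            gate=config.gate,
            trend_change=config.trend_change,
        )
        if call is not None:
            calls.append(call)
    log.done(f"{len(calls)} trend calls")

    return {
        "pair_qc": pair_qc,
        "per_sample": per_sample,
        "drivers": drivers,
        "calls": calls,
        "terminal": terminal,
        "cluster_graph": cgraph,
    }


def run_pipeline(config: RunConfig, outdir: str | Path | None = None) -> RunReport:
    violations = validate_config(config)
    if violations:
        raise ValueError("invalid config:\n" + "\n".join(violations))
    log = _StageLogger()

    # --- simulate -----------------------------------------------------
    log.start("simulate")
    genes = _build_genes(config)
    sim = SimulationConfig(**{**asdict(config.sim), "seed": _subseed(config.seed, 2)})
    pair = simulate_dataset(genes, sim)
    bound_ids = _bound_gene_ids(genes, config.bound_per_class, _subseed(config.seed, 3))
    genome = simulate_genome(genes, MotifSpec(bound_genes=bound_ids), seed=_subseed(config.seed, 4))
    log.done(f"{pair.n_cells} cells x {pair.n_genes} genes, {len(genome.peaks)} peaks")

    stages = analyze_pair(pair, config, log)
    pair_qc = stages["pair_qc"]
    per_sample = stages["per_sample"]
    drivers = stages["drivers"]
    calls = stages["calls"]
    terminal = stages["terminal"]
    term_cluster = str(terminal.cluster_score.idxmax())

    # --- binding and driver-target overlap ----------------------------
    log.start("binding")
    annotations = binding.annotate_peaks(
        genome.peaks, genome.gene_models, genome.tss_records, config.promoter_upstream
    )
    fractions = binding.category_fractions(annotations)
    bound = binding.peaks_to_genes(
        genome.peaks, genome.gene_models, genome.tss_records, config.promoter_upstream
    )
    dgt = binding.overlap_driver_targets(bound["gene_id"], drivers["gene_id"])
    dgt_calls = [c for c in calls if c.gene_id in set(dgt["dgt_genes"])]
    classification = trend.summarize_classification(dgt_calls)
    log.done(f"{dgt['n_overlap']} DGTs")

    # --- expression accounting ----------------------------------------
    log.start("expression")
    expr_mask = pair_qc.spliced.sum(axis=1) > 0
    norm = expression.log_normalize(pair_qc.spliced[expr_mask])
    meta = pair_qc.cell_meta.loc[expr_mask].reset_index(drop=True)
    deg_overlap = _deg_overlap(norm, meta, pair_qc.gene_meta["gene_id"])
    log.done("DEG overlap table built")

    report = RunReport(
        stage_counts={
            "n_cells_simulated": pair.n_cells,
            "n_cells_qc": pair_qc.n_cells,
            "n_genes": pair.n_genes,
            "n_peaks": len(genome.peaks),
            "n_bound_genes": dgt["n_bound"],
            "n_trend_calls": len(calls),
        },
        driver_count=len(drivers),
        dgt_count=dgt["n_overlap"],
        classification=classification,
        category_fractions=fractions,
        deg_overlap=deg_overlap,
        terminal_cluster=term_cluster,
        terminal_scores={str(k): float(v) for k, v in terminal.cluster_score.items()},
        config_fingerprint=_fingerprint(config),
    )

    if outdir is not None:
        _write_outputs(Path(outdir), config, pair, genome, per_sample, drivers, calls, report)
    return report


def _deg_overlap(norm: np.ndarray, meta: pd.DataFrame, gene_ids) -> pd.DataFrame:
    """DEGs of KO arrest vs WT late cluster, and KO-mid vs WT-mid; overlap."""
    def cells(sample, cluster):
        return ((meta["sample"] == sample) & (meta["cluster"] == cluster)).to_numpy()

    late = [c for c in meta.loc[meta["sample"] == "WT", "cluster"].unique() if c != ARREST_CLUSTER]
    late_cluster = sorted(late)[-1] if late else None
    mids = sorted(set(meta.loc[meta["sample"] == "KO", "cluster"]) - {ARREST_CLUSTER})
    empty = pd.DataFrame(
        columns=["direction", "denominator", "n_overlap", "n_set", "percent"]
    )
    if late_cluster is None or not mids or cells("KO", ARREST_CLUSTER).sum() < 10:
        return empty
    mid_cluster = mids[len(mids) // 2]
    try:
        deg_a = expression.differential_expression(
            norm[cells("KO", ARREST_CLUSTER)], norm[cells("WT", late_cluster)], gene_ids
        )
        deg_b = expression.differential_expression(
            norm[cells("KO", mid_cluster)], norm[cells("WT", mid_cluster)], gene_ids
        )
    except ValueError:
        return empty
    up = lambda degs: [d.gene_id for d in degs if d.direction == "up"]
    down = lambda degs: [d.gene_id for d in degs if d.direction == "down"]
    return expression.overlap_fractions(up(deg_a), up(deg_b), down(deg_a), down(deg_b))


def _fingerprint(config: RunConfig) -> str:
    import hashlib

    blob = json.dumps(
        {**asdict(config), "genes": None if config.genes is None else len(config.genes)},
        sort_keys=True,
        default=str,
    )
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _write_outputs(outdir, config, pair, genome, per_sample, drivers, calls, report):
    outdir.mkdir(parents=True, exist_ok=True)
    io.write_pair(pair, outdir / "counts")
    io.write_genome(genome, outdir / "genome")
    drivers.to_csv(outdir / "drivers.tsv", sep="\t", index=False)
    trend.calls_to_frame(calls).to_csv(outdir / "trend_calls.tsv", sep="\t", index=False)
    report.classification.to_csv(outdir / "classification.tsv", sep="\t", index=False)
    report.deg_overlap.to_csv(outdir / "deg_overlap.tsv", sep="\t", index=False)
    for sample, data in per_sample.items():
        pd.DataFrame(
            {
                "cell_id": data["pair"].cell_meta["cell_id"],
                "inferred_time": data["cell_time"],
            }
        ).to_csv(outdir / f"cell_time_{sample}.tsv", sep="\t", index=False)
        rows = [
            {
                "gene_id": f.gene_id,
                "alpha": f.alpha,
                "gamma": f.gamma,
                "t_switch": f.t_switch,
                "fit_likelihood": f.fit_likelihood,
                "valid": f.valid,
                "converged": f.converged,
            }
            for f in data["fits"]
        ]
        pd.DataFrame(rows).to_csv(outdir / f"fits_{sample}.tsv", sep="\t", index=False)
    manifest = {
        "config_fingerprint": report.config_fingerprint,
        "stage_counts": report.stage_counts,
        "driver_count": report.driver_count,
        "dgt_count": report.dgt_count,
        "terminal_cluster": report.terminal_cluster,
        "terminal_scores": report.terminal_scores,
        "category_fractions": {k: float(v) for k, v in report.category_fractions.items()},
        "classification": report.classification.to_dict(orient="records"),
    }
    with open(outdir / "report.json", "w") as fh:
        json.dump(manifest, fh, indent=2)


class _StageLogger:
    def __init__(self) -> None:
        import sys

        self.err = sys.stderr
        self.t0 = None
        self.stage = None

    def start(self, stage: str) -> None:
        self.stage = stage
        self.t0 = time.perf_counter()

    def done(self, msg: str) -> None:
        dt = time.perf_counter() - self.t0
        print(f"[pachydyn] {self.stage}: {msg} ({dt:.1f}s)", file=self.err)
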