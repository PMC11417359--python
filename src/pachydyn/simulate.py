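"""Synthetic two-sample spliced/unspliced data and a toy bound genome.

The generator produces everything the downstream pipeline consumes:

* paired spliced/unspliced count matrices for a wild-type (WT) and a
  knockout-like (KO) sample, drawn from a two-state transcription model
  with per-gene kinetic parameters and a gene class
  (induction / repression / steady);
* per-cell metadata (sample, cluster label along the trajectory, true
  latent time, QC covariates);
* a toy genome: contig sequences, TSS records, exon models, promoter
  peaks and a ledger of literally planted motif instances.

The KO perturbation has two components.  Flagged (ko_frozen) genes carry
the molecular lesion in every KO cell: repression genes keep
transcription ON (the switch-off never happens), induction genes never
switch on.  Independently, KO cells drawn past the arrest time stop
progressing: every other gene is evaluated at the arrest time instead of
the cell's nominal time, so arrested cells accumulate at a fixed,
reachable point of the trajectory.  Together these emulate a
differentiation arrest in which stage-exit genes stay highly transcribed
and stage-entry genes stall at their arrest-point level.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "KineticGene",
    "SimulationConfig",
    "CellMatrixPair",
    "ToyGenome",
    "MotifSpec",
    "kinetics_expected",
    "phase_expected",
    "simulate_dataset",
    "simulate_genome",
    "default_gene_panel",
]

GENE_CLASSES = ("induction", "repression", "steady")
ARREST_CLUSTER = "P-like"

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT",
    "K": "GT", "M": "AC", "B": "CGT", "D": "AGT",
    "H": "ACT", "V": "ACG", "N": "ACGT",
}

# Degenerate heptamer (T/A/C)(A/G)GAA(C/T)(G/C/A) and octamer
# GA(A/C)(C/G)C(T/G)(T/C)C found enriched under promoter-bound peaks.
HEPTAMER = "HRGAAYV"
OCTAMER = "GAMSCKYC"


@dataclass
class KineticGene:
    """Per-gene two-state transcription kinetics plus class label.

    alpha_on : transcription rate in the ON state (molecules / unit time)
    beta     : splicing rate (1 / unit time)
    gamma    : degradation rate (1 / unit time), distinct from beta
    t_switch : time of the transcription state change
    gene_class : 'induction' (OFF then ON), 'repression' (ON then OFF)
                 or 'steady' (constant ON)
    ko_frozen  : gene is perturbed in the KO sample
    """

    gene_id: str
    alpha_on: float
    beta: float
    gamma: float
    t_switch: float
    gene_class: str
    ko_frozen: bool = False

    def __post_init__(self) -> None:
        if self.alpha_on <= 0 or self.beta <= 0 or self.gamma <= 0:
            raise ValueError(
                f"{self.gene_id}: alpha_on, beta, gamma must be strictly positive"
            )
        if np.isclose(self.beta, self.gamma):
            raise ValueError(
                f"{self.gene_id}: beta == gamma degenerates the closed-form "
                "solution (the (gamma-beta) denominator vanishes); use "
                "distinct splicing and degradation rates"
            )
        if self.t_switch < 0:
            raise ValueError(f"{self.gene_id}: t_switch must be >= 0")
        if self.gene_class not in GENE_CLASSES:
            raise ValueError(f"{self.gene_id}: unknown gene_class {self.gene_class!r}")

    def steady_state(self) -> tuple[float, float]:
        """Fixed point (u, s) = (alpha/beta, alpha/gamma) of the ON state."""
        return self.alpha_on / self.beta, self.alpha_on / self.gamma


@dataclass
class SimulationConfig:
    """Study conditions for the two-sample simulation."""

    n_cells_per_sample: int = 500
    n_genes: int = 200
    time_distribution: tuple = ("uniform",)
    cluster_breakpoints: tuple[float, ...] = (1 / 3, 2 / 3)
    cluster_names: tuple[str, ...] = ("eP", "mP", "lP")
    ko_arrest_time: float = 0.5
    noise_model: str = "poisson"  # 'poisson' | 'negative_binomial' | 'none'
    nb_dispersion: float = 0.1
    capture_efficiency: float = 1.0
    round_counts: bool = True
    qc_outlier_fraction: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        bp = np.asarray(self.cluster_breakpoints, dtype=float)
        if bp.size and (np.any(np.diff(bp) <= 0) or bp.min() <= 0 or bp.max() >= 1):
            raise ValueError("cluster_breakpoints must be strictly increasing within (0, 1)")
        if len(self.cluster_names) != bp.size + 1:
            raise ValueError("need one cluster name per time bin (len(breakpoints)+1)")
        if not 0.0 <= self.ko_arrest_time <= 1.0:
            raise ValueError("ko_arrest_time must lie within [0, 1]")
        if self.noise_model not in ("poisson", "negative_binomial", "none"):
            raise ValueError(f"unknown noise_model {self.noise_model!r}")
        if not 0.0 < self.capture_efficiency <= 1.0:
            raise ValueError("capture_efficiency must lie in (0, 1]")
        if self.n_cells_per_sample <= 0:
            raise ValueError("n_cells_per_sample must be positive")
        if self.n_genes <= 0:
            raise ValueError("n_genes must be positive")


@dataclass
class CellMatrixPair:
    """Paired spliced/unspliced matrices with cell and gene metadata.

    Rows of both matrices and of ``cell_meta`` share one cell ordering;
    columns and ``gene_meta`` rows share one gene ordering.
    """

    spliced: np.ndarray
    unspliced: np.ndarray
    cell_meta: pd.DataFrame
    gene_meta: pd.DataFrame

    def __post_init__(self) -> None:
        if self.spliced.shape != self.unspliced.shape:
            raise ValueError("spliced and unspliced shapes differ")
        if self.spliced.shape[0] != len(self.cell_meta):
            raise ValueError("cell_meta length does not match matrix rows")
        if self.spliced.shape[1] != len(self.gene_meta):
            raise ValueError("gene_meta length does not match matrix columns")
        if (self.spliced < 0).any() or (self.unspliced < 0).any():
            raise ValueError("counts must be nonnegative")

    @property
    def n_cells(self) -> int:
        return self.spliced.shape[0]

    @property
    def n_genes(self) -> int:
        return self.spliced.shape[1]

    def subset_cells(self, mask: np.ndarray) -> "CellMatrixPair":
        return CellMatrixPair(
            self.spliced[mask],
            self.unspliced[mask],
            self.cell_meta.loc[mask].reset_index(drop=True),
            self.gene_meta,
        )

    def sample(self, name: str) -> "CellMatrixPair":
        return self.subset_cells((self.cell_meta["sample"] == name).to_numpy())


@dataclass
class ToyGenome:
    """Toy genome: contigs, TSS records, exon models, peaks, motif ledger.

    All intervals are 0-based half-open.  ``planted_motifs`` records
    (contig, position, strand, motif_id, sequence) for every literally
    planted instance; ``peak_genes`` maps each promoter peak to the gene
    it was planted for.
    """

    contigs: dict[str, str]
    tss_records: pd.DataFrame  # gene_id, contig, position, strand
    gene_models: pd.DataFrame  # gene_id, contig, start, end, strand, feature
    planted_motifs: pd.DataFrame  # contig, position, strand, motif_id, sequence
    peaks: pd.DataFrame  # contig, start, end, score
    peak_genes: pd.DataFrame  # contig, start, end, gene_id


def phase_expected(alpha, beta, gamma, tau, u0=0.0, s0=0.0):
    """Expected (u, s) after time ``tau`` in a phase of constant ``alpha``.

    Closed-form solution of du/dt = alpha - beta*u, ds/dt = beta*u - gamma*s
    from the initial condition (u0, s0).  Requires beta != gamma.
    """
    if np.isclose(beta, gamma):
        raise ValueError(
            "beta == gamma degenerates the closed form "
            "((gamma - beta) denominator); rates must be distinct"
        )
    tau = np.asarray(tau, dtype=float)
    if np.any(tau < -1e-12):
        raise ValueError("tau must be >= 0 (time since phase start)")
    tau = np.maximum(tau, 0.0)
    eb = np.exp(-beta * tau)
    eg = np.exp(-gamma * tau)
    u = u0 * eb + (alpha / beta) * (1.0 - eb)
    s = (
        s0 * eg
        + (alpha / gamma) * (1.0 - eg)
        + (alpha - beta * u0) / (gamma - beta) * (eg - eb)
    )
    return u, s


def _phase_schedule(gene: KineticGene, frozen: bool) -> list[tuple[float, float]]:
    """(start_time, alpha) phases for a gene, honouring the KO freeze."""
    if frozen:
        if gene.gene_class == "repression":
            return [(0.0, gene.alpha_on)]  # switch-off removed
        if gene.gene_class == "induction":
            return [(0.0, 0.0)]  # never switches on
    if gene.gene_class == "steady":
        return [(0.0, gene.alpha_on)]
    if gene.gene_class == "repression":
        return [(0.0, gene.alpha_on), (gene.t_switch, 0.0)]
    return [(0.0, 0.0), (gene.t_switch, gene.alpha_on)]  # induction


def _default_initial(gene: KineticGene) -> tuple[float, float]:
    # repression and steady genes begin at the ON fixed point; induction
    # genes begin silent.
    if gene.gene_class == "induction":
        return 0.0, 0.0
    return gene.steady_state()


def kinetics_expected(gene, t, phase_initial=None, frozen=False):
    """Expected (u, s) of ``gene`` at time(s) ``t``.

    The trajectory is continuous across the switch: the second phase
    starts from the first phase's value at ``t_switch``.  ``phase_initial``
    overrides the state at t = 0 (defaults: ON fixed point for repression
    and steady genes, (0, 0) for induction genes).  With ``frozen`` the KO
    perturbation is applied (no switch for perturbed classes).
    """
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("t must be >= 0")
    u0, s0 = phase_initial if phase_initial is not None else _default_initial(gene)
    phases = _phase_schedule(gene, frozen)
    u = np.zeros_like(t, dtype=float)
    s = np.zeros_like(t, dtype=float)
    state = (float(u0), float(s0))
    for i, (start, alpha) in enumerate(phases):
        end = phases[i + 1][0] if i + 1 < len(phases) else np.inf
        mask = (t >= start) & (t < end)
        if mask.any():
            ui, si = phase_expected(alpha, gene.beta, gene.gamma, t[mask] - start, *state)
            u[mask], s[mask] = ui, si
        if np.isfinite(end):
            state = phase_expected(alpha, gene.beta, gene.gamma, end - start, *state)
            state = (float(state[0]), float(state[1]))
    return np.maximum(u, 0.0), np.maximum(s, 0.0)


def default_gene_panel(
    n_repression: int = 80,
    n_induction: int = 60,
    n_steady: int = 60,
    seed: int = 0,
    ko_freeze: bool = True,
) -> list[KineticGene]:
    """Gene panel with field-realistic rate ranges.

    Rates are drawn log-uniformly: alpha in [0.5, 5] molecules/unit time
    (scaled x10 to a count scale for Poisson sampling), beta fixed at 1
    (time gauge), gamma/beta in [0.1, 2].  Repression genes switch off in
    [0.25, 0.45] and carry the KO lesion (``ko_frozen``) when
    ``ko_freeze`` is set; induction genes switch on in [0.15, 0.45] —
    rising through early and mid stage, which gives the mid-stage state
    its transcriptional identity — and stall through the arrest-time
    clamp rather than a molecular freeze, so the knockout trajectory
    keeps pre-arrest dynamics and a resolvable arrest state.
    """
    rng = np.random.default_rng(seed)
    genes: list[KineticGene] = []
    specs = (
        ("repression", n_repression, (0.25, 0.45), ko_freeze),
        ("induction", n_induction, (0.15, 0.45), False),
        ("steady", n_steady, (0.0, 0.0), False),
    )
    for gene_class, n, switch_range, frozen in specs:
        for i in range(n):
            alpha = float(np.exp(rng.uniform(np.log(0.5), np.log(5.0))))
            gamma = float(np.exp(rng.uniform(np.log(0.1), np.log(2.0))))
            if np.isclose(gamma, 1.0):
                gamma = 1.05
            t_switch = float(rng.uniform(*switch_range))
            genes.append(
                KineticGene(
                    gene_id=f"{gene_class[:3]}_{i:03d}",
                    alpha_on=10.0 * alpha,  # count scale for Poisson sampling
                    beta=1.0,
                    gamma=gamma,
                    t_switch=t_switch,
                    gene_class=gene_class,
                    ko_frozen=frozen,
                )
            )
    return genes


def _draw_times(rng: np.random.Generator, n: int, spec: tuple) -> np.ndarray:
    kind = spec[0]
    if kind == "uniform":
        return rng.uniform(0.0, 1.0, size=n)
    if kind == "beta":
        return rng.beta(spec[1], spec[2], size=n)
    raise ValueError(f"unknown time_distribution {spec!r}")


def _cluster_labels(times: np.ndarray, config: SimulationConfig) -> np.ndarray:
    bins = np.searchsorted(np.asarray(config.cluster_breakpoints), times, side="right")
    return np.asarray(config.cluster_names, dtype=object)[bins]


def expected_matrices(
    genes: Sequence[KineticGene],
    times: np.ndarray,
    ko: bool = False,
    arrest_time: float = 1.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Noise-free expected (unspliced, spliced) for cells x genes.

    With ``ko`` set, genes carrying ``ko_frozen`` follow the perturbed
    schedule in every cell (repression: switch-off removed; induction:
    never on), and all remaining genes are evaluated at
    min(time, arrest_time): cells drawn past the arrest stop progressing
    and sit at the trajectory's arrest point.
    """
    n_cells, n_genes = len(times), len(genes)
    U = np.empty((n_cells, n_genes))
    S = np.empty((n_cells, n_genes))
    clamped = np.minimum(times, arrest_time) if ko else times
    for j, gene in enumerate(genes):
        if ko and gene.ko_frozen:
            u, s = kinetics_expected(gene, times, frozen=True)
        else:
            u, s = kinetics_expected(gene, clamped if ko else times)
        U[:, j], S[:, j] = u, s
    return U, S


def _sample_counts(
    rng: np.random.Generator, expected: np.ndarray, config: SimulationConfig
) -> np.ndarray:
    lam = config.capture_efficiency * expected
    if config.noise_model == "poisson":
        return rng.poisson(lam).astype(np.int64)
    if config.noise_model == "negative_binomial":
        # NB with mean lam, variance lam + dispersion * lam^2
        disp = config.nb_dispersion
        if disp <= 0:
            return rng.poisson(lam).astype(np.int64)
        r = 1.0 / disp
        p = r / (r + np.maximum(lam, 1e-12))
        out = rng.negative_binomial(r, p)
        out[lam <= 0] = 0
        return out.astype(np.int64)
    if config.round_counts:
        return np.rint(lam).astype(np.int64)
    return lam


def simulate_dataset(
    genes: Sequence[KineticGene], config: SimulationConfig
) -> CellMatrixPair:
    """Simulate WT and KO cells along the trajectory.

    WT cells sample the unperturbed kinetics at their true time.  In the
    KO sample, ko_frozen genes follow the perturbed schedule (repression
    stays ON, induction stays off) and cells past ``ko_arrest_time``
    stop progressing (all other genes clamp to the arrest-time state)
    and are labelled with the arrest cluster.  QC covariates
    (genes_detected, mito_fraction) are drawn independently of the
    kinetics, with a small planted fraction of QC failures.
    """
    if not genes:
        raise ValueError("gene list is empty")
    rng = np.random.default_rng(config.seed)
    n = config.n_cells_per_sample

    frames = []
    mats_u, mats_s = [], []
    for sample in ("WT", "KO"):
        times = np.sort(_draw_times(rng, n, config.time_distribution))
        frozen = (sample == "KO") & (times > config.ko_arrest_time)
        U, S = expected_matrices(
            genes, times, ko=(sample == "KO"), arrest_time=config.ko_arrest_time
        )
        mats_u.append(_sample_counts(rng, U, config))
        mats_s.append(_sample_counts(rng, S, config))
        clusters = _cluster_labels(times, config)
        clusters[frozen] = ARREST_CLUSTER
        genes_detected = rng.integers(1500, 6000, size=n)
        mito = rng.beta(2.0, 30.0, size=n)
        n_bad = int(round(config.qc_outlier_fraction * n))
        if n_bad:
            bad = rng.choice(n, size=n_bad, replace=False)
            kind = rng.integers(0, 3, size=n_bad)
            genes_detected[bad[kind == 0]] = rng.integers(10, 201, size=(kind == 0).sum())
            genes_detected[bad[kind == 1]] = rng.integers(8500, 12000, size=(kind == 1).sum())
            mito[bad[kind == 2]] = rng.uniform(0.20, 0.6, size=(kind == 2).sum())
        frames.append(
            pd.DataFrame(
                {
                    "cell_id": [f"{sample}_{i:04d}" for i in range(n)],
                    "sample": sample,
                    "cluster": clusters,
                    "true_time": times,
                    "genes_detected": genes_detected,
                    "mito_fraction": mito,
                }
            )
        )

    cell_meta = pd.concat(frames, ignore_index=True)
    gene_meta = pd.DataFrame(
        {
            "gene_id": [g.gene_id for g in genes],
            "alpha_on": [g.alpha_on for g in genes],
            "beta": [g.beta for g in genes],
            "gamma": [g.gamma for g in genes],
            "t_switch": [g.t_switch for g in genes],
            "gene_class": [g.gene_class for g in genes],
            "ko_frozen": [g.ko_frozen for g in genes],
        }
    )
    return CellMatrixPair(
        spliced=np.vstack(mats_s),
        unspliced=np.vstack(mats_u),
        cell_meta=cell_meta,
        gene_meta=gene_meta,
    )


@dataclass
class MotifSpec:
    """What to plant in the toy genome.

    ``bound_genes``: gene ids that receive a promoter peak with at least
    one planted motif instance. ``motif_ids`` cycles over the planted
    instance types ('heptamer' draws a match of the degenerate heptamer,
    'hse' plants a 3-unit alternating nGAAn array).
    """

    bound_genes: Sequence[str] = ()
    motif_ids: Sequence[str] = ("heptamer", "hse")
    peak_halfwidth: int = 250
    gene_spacing: int = 4000
    n_background_peaks: int = 0


def _draw_iupac(rng: np.random.Generator, pattern: str) -> str:
    return "".join(rng.choice(list(IUPAC[c])) for c in pattern)


_COMP = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def _hse_instance(rng: np.random.Generator, n_units: int = 3) -> str:
    # alternating nGAAn / nTTCn pentamer units at period 5
    units = []
    start_fwd = bool(rng.integers(0, 2))
    for k in range(n_units):
        core = "GAA" if (k % 2 == 0) == start_fwd else "TTC"
        units.append(rng.choice(list("ACGT")) + core + rng.choice(list("ACGT")))
    return "".join(units)


def simulate_genome(
    genes: Sequence[KineticGene], motif_spec: MotifSpec, seed: int = 0
) -> ToyGenome:
    """Build a toy genome with planted promoter peaks and motifs.

    Each gene gets a TSS and a two-exon model on one contig; genes named
    in ``motif_spec.bound_genes`` get a peak centred within +/-500 bp of
    their TSS containing at least one planted heptamer or HSE instance.
    The planted-motif ledger records every instance literally written
    into the sequence.
    """
    rng = np.random.default_rng(seed)
    spacing = motif_spec.gene_spacing
    margin = 3000
    contig = "chrT"
    length = margin * 2 + spacing * len(genes)
    seq = rng.choice(list("ACGT"), size=length)

    tss_rows, model_rows = [], []
    for i, gene in enumerate(genes):
        strand = "+" if i % 2 == 0 else "-"
        pos = margin + i * spacing
        tss_rows.append((gene.gene_id, contig, pos, strand))
        # two exons downstream of the TSS in transcription direction
        if strand == "+":
            exons = [(pos, pos + 300), (pos + 800, pos + 1200)]
        else:
            exons = [(pos - 300, pos), (pos - 1200, pos - 800)]
        for start, end in exons:
            model_rows.append((gene.gene_id, contig, start, end, strand, "exon"))

    tss = pd.DataFrame(tss_rows, columns=["gene_id", "contig", "position", "strand"])
    models = pd.DataFrame(
        model_rows, columns=["gene_id", "contig", "start", "end", "strand", "feature"]
    )

    bound = list(motif_spec.bound_genes)
    unknown = set(bound) - set(tss["gene_id"])
    if unknown:
        raise ValueError(f"bound_genes not in the gene list: {sorted(unknown)}")

    peak_rows, ledger_rows, peak_gene_rows = [], [], []
    half = motif_spec.peak_halfwidth
    for i, gene_id in enumerate(bound):
        t = tss[tss["gene_id"] == gene_id].iloc[0]
        center = int(t["position"]) + int(rng.integers(-200, 201))
        start, end = max(0, center - half), min(length, center + half)
        motif_id = motif_spec.motif_ids[i % len(motif_spec.motif_ids)]
        if motif_id == "heptamer":
            inst = _draw_iupac(rng, HEPTAMER)
        elif motif_id == "octamer":
            inst = _draw_iupac(rng, OCTAMER)
        elif motif_id == "hse":
            inst = _hse_instance(rng)
        else:
            raise ValueError(f"unknown motif id {motif_id!r}")
        strand = "+" if rng.integers(0, 2) == 0 else "-"
        written = inst if strand == "+" else revcomp(inst)
        pos = int(rng.integers(start, end - len(written)))
        seq[pos : pos + len(written)] = list(written)
        peak_rows.append((contig, start, end, float(rng.uniform(5, 50))))
        ledger_rows.append((contig, pos, strand, motif_id, inst))
        peak_gene_rows.append((contig, start, end, gene_id))

    for _ in range(motif_spec.n_background_peaks):
        # intergenic decoys midway between adjacent promoters
        i = int(rng.integers(0, len(genes) - 1)) if len(genes) > 1 else 0
        center = margin + i * spacing + spacing // 2
        peak_rows.append((contig, center - half, center + half, float(rng.uniform(1, 5))))

    genome = ToyGenome(
        contigs={contig: "".join(seq)},
        tss_records=tss,
        gene_models=models,
        planted_motifs=pd.DataFrame(
            ledger_rows, columns=["contig", "position", "strand", "motif_id", "sequence"]
        ),
        peaks=pd.DataFrame(peak_rows, columns=["contig", "start", "end", "score"]),
        peak_genes=pd.DataFrame(
            peak_gene_rows, columns=["contig", "start", "end", "gene_id"]
        ),
    )
    _check_ledger(genome)
    return genome


def _check_ledger(genome: ToyGenome) -> None:
    for row in genome.planted_motifs.itertuples():
        sub = genome.contigs[row.contig][row.position : row.position + len(row.sequence)]
        expected = row.sequence if row.strand == "+" else revcomp(row.sequence)
        if sub != expected:
            raise AssertionError(
                f"planted motif ledger inconsistent at {row.contig}:{row.position}"
            )
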