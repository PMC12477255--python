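"""Synthetic mass-cytometry experiment generator.

Generates fully specified experiments — a ground-truth object plus raw
barcoded event streams — with the statistical structure the downstream
analysis assumes: three treatment groups (mock / mRNA / protein, n animals
each), two tissues (PBMC, mediastinal LN), three short *ex vivo* stimulation
conditions (unstimulated PBS control, PMA/ionomycin, R848), 13 mononuclear
populations drawn as a mixture, spiked normalization beads, palladium
k-of-n barcoding, smooth time-dependent sensitivity drift, and per-animal
clinical outcomes linked to a latent severity variable.

Marker intensities are Gaussian on the arcsinh(x/5) scale, back-transformed
with ``x = 5·sinh(z)`` and left-truncated at zero; stimulation effects are
additive shifts on the arcsinh scale of the signaling channels.  Every draw
is a pure function of ``(config, seed)``: repeated calls with the same
arguments return identical values.

True per-event labels (population, bead flag, source sample) are emitted in
a sidecar table that is never written into the event channels, so the
analysis pipeline cannot read them.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .panel import Panel, BarcodeScheme, TIME_CHANNEL, default_panel, default_scheme

COFACTOR = 5.0

GROUPS = ("mock", "mRNA", "protein")
TISSUES = ("PBMC", "LN")
STIMS = ("UNSTIM", "PMAI", "R848")

#: the 13 disjoint generator components (reported populations; nested gates
#: aggregate CD8T_act into CD8T and B_IgM into B)
POPULATIONS = (
    "CD4T", "CD8T", "CD8T_act", "DNT", "B", "B_IgM",
    "NK_CD56", "NK_CD16", "pDC", "mDC", "cMC", "intMC", "ncMC",
)
_EXTRA = ("other", "granulocyte")
ALL_COMPONENTS = POPULATIONS + _EXTRA

#: phenotype markers positive per component; everything else is negative
_POSITIVE = {
    "CD4T": {"CD45", "CD3", "CD4"},
    "CD8T": {"CD45", "CD3", "CD8"},
    "CD8T_act": {"CD45", "CD3", "CD8", "HLA-DR", "Ki67"},
    "DNT": {"CD45", "CD3"},
    "B": {"CD45", "CD20", "HLA-DR"},
    "B_IgM": {"CD45", "CD20", "IgM", "HLA-DR"},
    "NK_CD56": {"CD45", "CD56"},
    "NK_CD16": {"CD45", "CD16", "CD11b"},
    "pDC": {"CD45", "CD123", "HLA-DR"},
    "mDC": {"CD45", "CD11c", "HLA-DR"},
    "cMC": {"CD45", "CD14", "CD11b", "CD11c", "HLA-DR"},
    "intMC": {"CD45", "CD14", "CD16", "CD11b", "CD11c", "HLA-DR"},
    "ncMC": {"CD45", "CD16", "CD11c", "HLA-DR"},
    "other": {"CD45"},
    "granulocyte": {"CD45", "CD66", "CD16", "CD11b"},
}

_BASE_FREQS = {
    "PBMC": {
        "CD4T": 0.30, "CD8T": 0.15, "CD8T_act": 0.004, "DNT": 0.03,
        "B": 0.09, "B_IgM": 0.04, "NK_CD56": 0.02, "NK_CD16": 0.06,
        "pDC": 0.006, "mDC": 0.010, "cMC": 0.10, "intMC": 0.015,
        "ncMC": 0.012,
    },
    "LN": {
        "CD4T": 0.33, "CD8T": 0.13, "CD8T_act": 0.003, "DNT": 0.02,
        "B": 0.20, "B_IgM": 0.07, "NK_CD56": 0.01, "NK_CD16": 0.01,
        "pDC": 0.006, "mDC": 0.008, "cMC": 0.012, "intMC": 0.005,
        "ncMC": 0.004,
    },
}

# multiplicative frequency effects relative to the vaccinated baseline;
# mirrors the headline composition pattern: more activated CD8 T cells and
# fewer pDC in unvaccinated blood, more intermediate monocytes and B cells
# in unvaccinated lymph node
_GROUP_EFFECTS = {
    ("PBMC", "mock", "CD8T_act"): 3.5,
    ("PBMC", "mock", "pDC"): 0.33,
    ("LN", "mock", "intMC"): 3.0,
    ("LN", "mock", "B"): 1.4,
    ("LN", "mock", "B_IgM"): 1.7,
}

_T_CELLS = ("CD4T", "CD8T", "CD8T_act", "DNT")
_B_CELLS = ("B", "B_IgM")
_NK = ("NK_CD56", "NK_CD16")
_MYELOID = ("cMC", "intMC", "ncMC", "mDC")


def _default_stim_effects() -> dict:
    """Additive arcsinh shifts per (population, signaling marker, stim)."""
    eff: dict[tuple[str, str, str], float] = {}

    def add(pops, marker, stim, delta):
        for p in pops:
            eff[(p, marker, stim)] = delta

    # PMA/ionomycin: broad PKC/calcium-driven MAPK and CREB activation
    add(_T_CELLS, "pErk1/2", "PMAI", 1.2)
    add(_NK, "pErk1/2", "PMAI", 1.0)
    add(_B_CELLS, "pErk1/2", "PMAI", 0.8)
    add(_MYELOID, "pErk1/2", "PMAI", 0.9)
    add(("pDC",), "pErk1/2", "PMAI", 0.6)
    add(_T_CELLS, "pCREB", "PMAI", 0.7)
    add(_NK, "pCREB", "PMAI", 0.9)
    add(_B_CELLS, "pCREB", "PMAI", 0.6)
    add(_MYELOID, "pCREB", "PMAI", 0.8)
    add(_T_CELLS + _NK + _B_CELLS + _MYELOID, "pP38", "PMAI", 0.8)
    add(_T_CELLS + _NK + _B_CELLS + _MYELOID, "pMAPKAP2", "PMAI", 0.7)
    add(_T_CELLS, "pS6", "PMAI", 0.5)
    add(_B_CELLS, "IkBa", "PMAI", -0.5)
    # R848 (TLR7/8): pDC, monocytes and B cells respond
    add(("pDC",), "pErk1/2", "R848", 0.7)
    add(_MYELOID, "pErk1/2", "R848", 0.5)
    add(_B_CELLS, "pErk1/2", "R848", 0.3)
    add(("pDC",), "pP38", "R848", 0.6)
    add(_MYELOID, "pP38", "R848", 0.5)
    add(("pDC",), "pTBK1", "R848", 0.5)
    add(("pDC",), "IkBa", "R848", -0.4)
    add(_B_CELLS, "IkBa", "R848", -0.5)
    add(_MYELOID, "IkBa", "R848", -0.3)
    return eff


@dataclass
class TruthConfig:
    """All knobs of the generator; defaults are the study conditions."""

    groups: dict = field(default_factory=lambda: {g: 8 for g in GROUPS})
    tissues: tuple = TISSUES
    stims: tuple = STIMS
    populations: tuple = POPULATIONS
    base_freqs: dict = field(default_factory=lambda: {
        t: dict(v) for t, v in _BASE_FREQS.items()})
    group_effects: dict = field(default_factory=lambda: dict(_GROUP_EFFECTS))
    granulocyte_fraction: float = 0.04
    animal_jitter_sd: float = 0.12      # lognormal sd on per-animal fractions

    positive_level: float = 4.0         # arcsinh-scale location, positive mode
    negative_level: float = 0.35        # arcsinh-scale location, negative mode
    marker_sd: float = 0.30
    signaling_baseline: float = 1.0
    baseline_jitter_sd: float = 0.05    # per-(animal, tissue, marker)

    stim_effects: dict = field(default_factory=_default_stim_effects)
    response_noise_sd: float = 0.05     # per-(animal, tissue, pop, marker, stim)

    barcode_high: float = 5.5
    barcode_low: float = 0.3
    barcode_sd: float = 0.25
    bead_level: float = 4.0
    bead_sd: float = 0.20
    bead_background: float = 0.10       # bead channels on cell events

    # global instrument sensitivity m(t) = c0 + c1·u + c2·u², u = t/window
    drift_coeffs: tuple = (1.0, -0.25, 0.10)
    channel_drift: dict = field(default_factory=dict)  # per-channel override
    time_window: float = 600.0

    severity_mu: dict = field(default_factory=lambda: {
        "mock": 2.4, "mRNA": 1.2, "protein": 0.8})
    severity_sd: float = 0.45
    severity_ref: float = 1.5
    severity_freq_coupling: dict = field(default_factory=lambda: {
        ("PBMC", "CD8T_act"): 0.35,
        ("LN", "intMC"): 0.35,
        ("PBMC", "pDC"): -0.30,
    })
    severity_signal_coupling: dict = field(default_factory=lambda: {
        ("PBMC", "NK_CD56", "pCREB", "PMAI"): 0.30,
        ("LN", "B_IgM", "IkBa", "PMAI"): -0.30,
    })
    # outcome = intercept + slope·severity + N(0, noise), clipped to range
    outcome_links: dict = field(default_factory=lambda: {
        "viral_rna_log10": (2.5, 1.3, 0.45, (0.0, 10.0)),
        "pathology_score": (0.4, 0.9, 0.30, (0.0, 4.0)),
        "radiograph_score": (0.2, 0.6, 0.25, (0.0, 3.0)),
    })

    cbc_wbc_mean: float = 9500.0        # cells/µL, lognormal location
    cbc_wbc_sd: float = 0.25

    def validate(self) -> None:
        for t, freqs in self.base_freqs.items():
            vals = np.array(list(freqs.values()), dtype=float)
            if (vals < 0).any() or (vals > 1).any():
                raise ValueError(f"population fractions outside [0,1] for {t}")
            if vals.sum() > 1.0 + 1e-12:
                raise ValueError(
                    f"population fractions sum to {vals.sum():.3f} > 1 for {t}")
            unknown = set(freqs) - set(self.populations)
            if unknown:
                raise ValueError(f"unknown populations in base_freqs: {unknown}")
        for g, n in self.groups.items():
            if n < 0 or int(n) != n:
                raise ValueError(f"negative or non-integer n_animals for {g}")
        if not (0 < self.marker_sd and 0 < self.barcode_sd):
            raise ValueError("marker/barcode sd must be positive")
        unknown = set(self.populations) - set(POPULATIONS)
        if unknown:
            raise ValueError(f"unknown populations: {unknown}")


@dataclass(frozen=True)
class SampleMeta:
    animal_id: str
    group: str
    tissue: str
    stim: str
    barcode_code: tuple[int, ...] = ()
    batch_id: str = "batch1"

    @property
    def sample_id(self) -> str:
        return f"{self.animal_id}_{self.tissue}_{self.stim}"


@dataclass(frozen=True)
class CBCRecord:
    animal_id: str
    wbc: float
    neutrophils: float
    eosinophils: float

    def __post_init__(self) -> None:
        if not (self.wbc >= self.neutrophils + self.eosinophils >= 0):
            raise ValueError("CBC invariant violated: wbc < neut + eos")

    @property
    def mononuclear_per_ul(self) -> float:
        return self.wbc - (self.neutrophils + self.eosinophils)


@dataclass(frozen=True)
class OutcomeRecord:
    animal_id: str
    viral_rna_log10: float
    pathology_score: float
    radiograph_score: float

    def __post_init__(self) -> None:
        if not 0 <= self.pathology_score <= 4:
            raise ValueError("pathology score outside [0, 4]")
        if not 0 <= self.radiograph_score <= 3:
            raise ValueError("radiograph score outside [0, 3]")


@dataclass
class EventMatrix:
    """Events × channels with acquisition time, plus optional truth sidecar."""

    data: pd.DataFrame
    panel: Panel
    truth: pd.DataFrame | None = None

    @property
    def n_events(self) -> int:
        return len(self.data)

    def copy(self) -> "EventMatrix":
        return EventMatrix(self.data.copy(), self.panel,
                           None if self.truth is None else self.truth.copy())


def _rng(seed: int, *tokens) -> np.random.Generator:
    entropy = [int(seed) & 0x7FFFFFFF]
    for t in tokens:
        entropy.append(zlib.crc32(str(t).encode()))
    return np.random.default_rng(np.random.SeedSequence(entropy))


@dataclass
class ExperimentTruth:
    """Ground truth for one synthetic experiment."""

    config: TruthConfig
    seed: int
    panel: Panel
    animals: list          # (animal_id, group)
    severity: dict         # animal_id -> latent severity
    fractions: dict        # (animal_id, tissue) -> array over ALL_COMPONENTS

    @property
    def animal_ids(self) -> list[str]:
        return [a for a, _ in self.animals]

    def group_of(self, animal_id: str) -> str:
        for a, g in self.animals:
            if a == animal_id:
                return g
        raise KeyError(f"unknown animal {animal_id!r}")

    def component_fractions(self, animal_id: str, tissue: str) -> np.ndarray:
        key = (animal_id, tissue)
        if key not in self.fractions:
            raise KeyError(f"unknown (animal, tissue) {key}")
        return self.fractions[key]

    def expected_frequency(self, animal_id: str, tissue: str, population: str
                           ) -> float:
        """True frequency (% of mononuclear events) of a reported population.

        Nested populations aggregate their components: CD8T includes
        CD8T_act, B includes B_IgM.
        """
        comps = {population}
        comps |= {"CD8T_act"} if population == "CD8T" else set()
        comps |= {"B_IgM"} if population == "B" else set()
        f = self.component_fractions(animal_id, tissue)
        mono = 1.0 - f[ALL_COMPONENTS.index("granulocyte")]
        num = sum(f[ALL_COMPONENTS.index(c)] for c in comps)
        return 100.0 * num / mono

    # ---- signaling truth -------------------------------------------------

    def baseline_offset(self, animal_id: str, tissue: str) -> np.ndarray:
        """Per-signaling-channel baseline offset for one (animal, tissue)."""
        rng = _rng(self.seed, "baseline", animal_id, tissue)
        n = len(self.panel.signaling_channels)
        return rng.normal(0.0, self.config.baseline_jitter_sd, size=n)

    def stim_shift_matrix(self, meta: SampleMeta) -> np.ndarray:
        """Realized arcsinh shifts, components × signaling channels.

        Zero for UNSTIM.  For stimulated samples: configured base shift,
        plus severity coupling for designated features, plus a per-sample
        reproducible response-noise draw.
        """
        cfg = self.config
        sig = self.panel.signaling_channels
        shifts = np.zeros((len(ALL_COMPONENTS), len(sig)))
        if meta.stim == "UNSTIM":
            return shifts
        sev = self.severity[meta.animal_id] - cfg.severity_ref
        rng = _rng(self.seed, "resp", meta.animal_id, meta.tissue, meta.stim)
        noise = rng.normal(0.0, cfg.response_noise_sd, size=shifts.shape)
        for i, pop in enumerate(ALL_COMPONENTS):
            for j, marker in enumerate(sig):
                base = cfg.stim_effects.get((pop, marker, meta.stim), 0.0)
                beta = cfg.severity_signal_coupling.get(
                    (meta.tissue, pop, marker, meta.stim), 0.0)
                if base != 0.0 or beta != 0.0:
                    shifts[i, j] = base + beta * sev + noise[i, j]
        return shifts

    # ---- drift -----------------------------------------------------------

    def drift(self, channel: str, t: np.ndarray) -> np.ndarray:
        """Multiplicative sensitivity for a channel at acquisition time t."""
        cfg = self.config
        coeffs = cfg.channel_drift.get(channel, cfg.drift_coeffs)
        u = np.asarray(t, dtype=float) / cfg.time_window
        m = np.zeros_like(u)
        for k, c in enumerate(coeffs):
            m = m + c * u ** k
        return m


def make_truth(config: TruthConfig | None = None, seed: int = 0,
               panel: Panel | None = None) -> ExperimentTruth:
    """Build the ground-truth object for one experiment.

    Deterministic in ``(config, seed)``.  Per-animal latent severities are
    drawn with group-dependent means; per-(animal, tissue) population
    fractions apply the configured group effects, severity couplings and
    lognormal animal-to-animal jitter, then are renormalized if needed so the
    mononuclear components plus an unlabeled remainder stay on the simplex.
    """
    config = config or TruthConfig()
    config.validate()
    panel = panel or default_panel()

    rng = _rng(seed, "truth")
    animals = []
    for g in config.groups:
        for i in range(int(config.groups[g])):
            animals.append((f"{g}{i+1:02d}", g))

    severity = {}
    for a, g in animals:
        severity[a] = float(rng.normal(config.severity_mu[g],
                                       config.severity_sd))

    gran = config.granulocyte_fraction
    fractions = {}
    for a, g in animals:
        sev = severity[a] - config.severity_ref
        for t in config.tissues:
            f = np.zeros(len(ALL_COMPONENTS))
            for pop in config.populations:
                base = config.base_freqs[t].get(pop, 0.0)
                mult = config.group_effects.get((t, g, pop), 1.0)
                beta = config.severity_freq_coupling.get((t, pop), 0.0)
                jit = rng.lognormal(0.0, config.animal_jitter_sd) \
                    if config.animal_jitter_sd > 0 else 1.0
                f[ALL_COMPONENTS.index(pop)] = (
                    base * mult * np.exp(beta * sev) * jit)
            named = f.sum()
            mono_budget = (1.0 - gran) * 0.97
            if named > mono_budget:
                f *= mono_budget / named
                named = mono_budget
            f[ALL_COMPONENTS.index("granulocyte")] = gran
            f[ALL_COMPONENTS.index("other")] = 1.0 - gran - named
            fractions[(a, t)] = f

    truth = ExperimentTruth(config=config, seed=seed, panel=panel,
                            animals=animals, severity=severity,
                            fractions=fractions)
    # invariant: drift strictly positive over the acquisition window
    grid = np.linspace(0, config.time_window, 101)
    for ch in panel.measurement_channels:
        if (truth.drift(ch, grid) <= 0).any():
            raise ValueError(f"drift multiplier non-positive on {ch}")
    return truth


# ---------------------------------------------------------------------------
# event simulation
# ---------------------------------------------------------------------------

def _marker_locs(truth: ExperimentTruth) -> np.ndarray:
    """Components × (phenotype+signaling) arcsinh-scale locations."""
    cfg = truth.config
    pheno = truth.panel.phenotype_channels
    sig = truth.panel.signaling_channels
    locs = np.zeros((len(ALL_COMPONENTS), len(pheno) + len(sig)))
    for i, pop in enumerate(ALL_COMPONENTS):
        pos = _POSITIVE[pop]
        for j, m in enumerate(pheno):
            locs[i, j] = cfg.positive_level if m in pos else cfg.negative_level
        locs[i, len(pheno):] = cfg.signaling_baseline
    return locs


def _simulate_cells(truth: ExperimentTruth, meta: SampleMeta, n: int,
                    rng: np.random.Generator,
                    apply_drift: bool = True,
                    times: np.ndarray | None = None):
    """Raw intensities for n cell events; returns (raw df cols, pop labels, t)."""
    cfg = truth.config
    panel = truth.panel
    pheno = panel.phenotype_channels
    sig = panel.signaling_channels
    nb = len(panel.barcode_channels)

    probs = truth.component_fractions(meta.animal_id, meta.tissue)
    probs = probs / probs.sum()
    pop_idx = rng.choice(len(ALL_COMPONENTS), size=n, p=probs)

    locs = _marker_locs(truth)[pop_idx, :]
    # baseline offsets and stimulation shifts on signaling channels
    locs[:, len(pheno):] += truth.baseline_offset(meta.animal_id, meta.tissue)
    locs[:, len(pheno):] += truth.stim_shift_matrix(meta)[pop_idx, :]
    z = rng.normal(locs, cfg.marker_sd)
    raw = np.maximum(COFACTOR * np.sinh(z), 0.0)

    # barcode channels: high on the k code positions, low elsewhere
    code = np.asarray(meta.barcode_code, dtype=float)
    if code.size == 0:
        code = np.zeros(nb)
    if code.size != nb:
        raise ValueError(f"barcode code length {code.size} != {nb} channels")
    bc_loc = np.where(code > 0, cfg.barcode_high, cfg.barcode_low)
    z_bc = rng.normal(np.broadcast_to(bc_loc, (n, nb)), cfg.barcode_sd)
    raw_bc = np.maximum(COFACTOR * np.sinh(z_bc), 0.0)

    # bead channels: low background on cell events
    nbe = len(panel.bead_channels)
    z_bd = rng.normal(cfg.bead_background, cfg.marker_sd, size=(n, nbe))
    raw_bd = np.maximum(COFACTOR * np.sinh(z_bd), 0.0)

    if times is None:
        times = np.sort(rng.uniform(0.0, cfg.time_window, size=n))
        times = times + np.arange(n) * 1e-9      # strictly increasing
    mat = np.hstack([raw, raw_bc, raw_bd])
    cols = pheno + sig + panel.barcode_channels + panel.bead_channels
    if apply_drift:
        for j, ch in enumerate(cols):
            mat[:, j] = mat[:, j] * truth.drift(ch, times)
    labels = np.array([ALL_COMPONENTS[i] for i in pop_idx])
    return mat, cols, labels, times


def simulate_sample(truth: ExperimentTruth, meta: SampleMeta,
                    n_events: int = 50_000, bead_fraction: float = 0.03,
                    apply_drift: bool = True) -> EventMatrix:
    """Simulate one acquired sample: cell events plus spiked beads.

    Bead events carry the five-channel bead signature and near-zero antibody
    and barcode signal; cell events carry the population mixture for the
    sample's (animal, tissue), the configured stimulation shifts, the
    sample's palladium code, and multiplicative sensitivity drift.
    """
    if n_events < 1:
        raise ValueError("n_events must be >= 1")
    if not 0.0 <= bead_fraction <= 0.2:
        raise ValueError("bead_fraction must be in [0, 0.2]")
    if meta.tissue not in truth.config.tissues:
        raise ValueError(f"unknown tissue {meta.tissue!r}")
    if meta.stim not in truth.config.stims:
        raise ValueError(f"unknown stim {meta.stim!r}")
    truth.group_of(meta.animal_id)   # raises on unknown animal

    cfg = truth.config
    panel = truth.panel
    rng = _rng(truth.seed, "sample", meta.animal_id, meta.tissue, meta.stim,
               meta.batch_id)
    n_beads = int(rng.binomial(n_events, bead_fraction)) if bead_fraction else 0
    n_cells = n_events - n_beads

    mat, cols, labels, t_cells = _simulate_cells(
        truth, meta, n_cells, rng, apply_drift=apply_drift)

    if n_beads:
        nbe = len(panel.bead_channels)
        n_other = len(cols) - nbe
        z_bd = rng.normal(cfg.bead_level, cfg.bead_sd, size=(n_beads, nbe))
        bead_sig = np.maximum(COFACTOR * np.sinh(z_bd), 0.0)
        bead_bg = np.abs(rng.normal(0.0, 0.2, size=(n_beads, n_other)))
        t_beads = np.sort(rng.uniform(0.0, cfg.time_window, size=n_beads))
        bmat = np.hstack([bead_bg, bead_sig])
        if apply_drift:
            for j, ch in enumerate(cols):
                bmat[:, j] = bmat[:, j] * truth.drift(ch, t_beads)
        mat = np.vstack([mat, bmat])
        labels = np.concatenate([labels, np.array(["bead"] * n_beads)])
        times = np.concatenate([t_cells, t_beads])
        order = np.argsort(times, kind="stable")
        mat, labels, times = mat[order], labels[order], times[order]
        times = times + np.arange(len(times)) * 1e-9
    else:
        times = t_cells

    df = pd.DataFrame(mat, columns=cols)
    # reorder to panel measurement order and append time
    df = df[panel.measurement_channels]
    df[TIME_CHANNEL] = times
    sidecar = pd.DataFrame({
        "population": labels,
        "is_bead": labels == "bead",
        "is_doublet": False,
        "sample_id": meta.sample_id,
    })
    return EventMatrix(df, panel, sidecar)


def simulate_doublet_events(truth: ExperimentTruth, meta_a: SampleMeta,
                            meta_b: SampleMeta, n: int) -> EventMatrix:
    """Cell–cell doublets spanning two barcoded samples.

    Each doublet's intensities are the channel-wise sum of one event from
    each sample, so its barcode signal is the union of two distinct codes
    (more than k channels high).
    """
    if tuple(meta_a.barcode_code) == tuple(meta_b.barcode_code):
        raise ValueError("doublet members must carry distinct barcode codes")
    panel = truth.panel
    cols = panel.measurement_channels
    if n == 0:
        df = pd.DataFrame(np.zeros((0, len(cols) + 1)),
                          columns=cols + [TIME_CHANNEL])
        sidecar = pd.DataFrame({"population": [], "is_bead": [],
                                "is_doublet": [], "sample_id": []})
        return EventMatrix(df, panel, sidecar)
    rng = _rng(truth.seed, "doublet", meta_a.sample_id, meta_b.sample_id)
    times = np.sort(rng.uniform(0.0, truth.config.time_window, size=n))
    times = times + np.arange(n) * 1e-9
    mat_a, raw_cols, _, _ = _simulate_cells(truth, meta_a, n, rng,
                                            apply_drift=True, times=times)
    mat_b, _, _, _ = _simulate_cells(truth, meta_b, n, rng,
                                     apply_drift=True, times=times)
    mat = mat_a + mat_b
    df = pd.DataFrame(mat, columns=raw_cols)[cols]
    df[TIME_CHANNEL] = times
    sidecar = pd.DataFrame({
        "population": ["doublet"] * n,
        "is_bead": False,
        "is_doublet": True,
        "sample_id": "DOUBLET",
    })
    return EventMatrix(df, panel, sidecar)


def concat_events(parts: list[EventMatrix]) -> EventMatrix:
    """Pool event matrices and sort by acquisition time."""
    panel = parts[0].panel
    data = pd.concat([p.data for p in parts], ignore_index=True)
    truth = pd.concat([p.truth for p in parts], ignore_index=True) \
        if all(p.truth is not None for p in parts) else None
    order = np.argsort(data[TIME_CHANNEL].to_numpy(), kind="stable")
    data = data.iloc[order].reset_index(drop=True)
    data[TIME_CHANNEL] = (data[TIME_CHANNEL].to_numpy()
                          + np.arange(len(data)) * 1e-9)
    if truth is not None:
        truth = truth.iloc[order].reset_index(drop=True)
    return EventMatrix(data, panel, truth)


def simulate_batch(truth: ExperimentTruth, metas: list[SampleMeta],
                   n_events: int = 50_000, bead_fraction: float = 0.03,
                   doublet_rate: float = 0.0,
                   apply_drift: bool = True) -> tuple[EventMatrix, BarcodeScheme]:
    """Simulate one pooled barcoded batch (typically 16 samples).

    Assigns k-of-n codes to the samples (unless already set on the metas),
    simulates each sample over a shared acquisition window, optionally adds
    cross-sample doublets, and pools everything ordered by time.
    """
    ids = [m.sample_id for m in metas]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate (animal, tissue, stim) within batch")
    if all(len(m.barcode_code) for m in metas):
        scheme = BarcodeScheme({m.sample_id: tuple(m.barcode_code)
                                for m in metas})
    else:
        scheme = default_scheme(ids)
        metas = [replace(m, barcode_code=scheme.codes[m.sample_id])
                 for m in metas]
    parts = [simulate_sample(truth, m, n_events, bead_fraction,
                             apply_drift=apply_drift) for m in metas]
    if doublet_rate > 0 and len(metas) >= 2:
        n_doub = int(round(doublet_rate * n_events * len(metas)))
        rng = _rng(truth.seed, "doubletpairs", metas[0].batch_id)
        per_pair = max(1, n_doub // max(1, len(metas) // 2))
        made = 0
        while made < n_doub:
            i, j = rng.choice(len(metas), size=2, replace=False)
            k = min(per_pair, n_doub - made)
            parts.append(simulate_doublet_events(truth, metas[i], metas[j], k))
            made += k
    return concat_events(parts), scheme


# ---------------------------------------------------------------------------
# clinical data
# ---------------------------------------------------------------------------

def simulate_cbc(truth: ExperimentTruth, animal_id: str) -> CBCRecord:
    """Complete blood count; the mononuclear invariant holds by construction."""
    truth.group_of(animal_id)
    cfg = truth.config
    rng = _rng(truth.seed, "cbc", animal_id)
    wbc = rng.lognormal(np.log(cfg.cbc_wbc_mean), cfg.cbc_wbc_sd)
    neut_frac = float(np.clip(rng.normal(0.45, 0.08), 0.10, 0.80))
    eos_frac = float(np.clip(rng.normal(0.03, 0.015), 0.0, 0.10))
    return CBCRecord(animal_id=animal_id, wbc=float(wbc),
                     neutrophils=float(wbc * neut_frac),
                     eosinophils=float(wbc * eos_frac))


def simulate_outcomes(truth: ExperimentTruth, animal_id: str) -> OutcomeRecord:
    """Clinical outcomes as linear links to latent severity plus noise."""
    truth.group_of(animal_id)
    cfg = truth.config
    sev = truth.severity[animal_id]
    rng = _rng(truth.seed, "outcome", animal_id)
    vals = {}
    for name, (b0, b1, noise, (lo, hi)) in cfg.outcome_links.items():
        v = b0 + b1 * sev + (rng.normal(0.0, noise) if noise > 0 else 0.0)
        vals[name] = float(np.clip(v, lo, hi))
    return OutcomeRecord(animal_id=animal_id, **vals)


def outcome_table(truth: ExperimentTruth) -> pd.DataFrame:
    rows = [vars(simulate_outcomes(truth, a)) for a in truth.animal_ids]
    return pd.DataFrame(rows)


def cbc_table(truth: ExperimentTruth) -> pd.DataFrame:
    rows = [vars(simulate_cbc(truth, a)) for a in truth.animal_ids]
    return pd.DataFrame(rows)


def experiment_metas(truth: ExperimentTruth, batch_size: int = 16
                     ) -> list[list[SampleMeta]]:
    """All (animal × tissue × stim) samples grouped into barcoded batches."""
    metas = []
    for a, g in truth.animals:
        for t in truth.config.tissues:
            for s in truth.config.stims:
                metas.append(SampleMeta(animal_id=a, group=g, tissue=t, stim=s))
    batches = []
    for i in range(0, len(metas), batch_size):
        chunk = [replace(m, batch_id=f"batch{i // batch_size + 1}")
                 for m in metas[i:i + batch_size]]
        batches.append(chunk)
    return batches
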