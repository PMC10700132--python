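"""Synthetic screens with planted ground truth.

Every downstream stage of the pipeline is testable without external data:
the generator plants co-functional TF modules, co-regulated gene programmes,
cell states, an abundance profile over perturbations, and direct-capture
sgRNA noise, then draws a cell × gene UMI matrix and a cell × sgRNA UMI
matrix from an explicit generative model:

* cell state ~ categorical(prevalences); perturbation target ~ abundance
  profile; the infecting construct is uniform among the target's constructs.
* expression count ~ NegBin(mean = L_c · μ_g · 2^{E[module(target),
  programme(g)]} · state multiplier, dispersion θ), with lognormal per-cell
  library-size factors L_c. Effects are multiplicative on the mean, so the
  log2 fold-change estimand of downstream DE equals the planted E directly.
* sgRNA UMIs: each guide of the captured construct ~ Poisson(λ_true); every
  guide accrues ambient background ~ Poisson(λ_background); doublets carry a
  second construct; a fraction of cells fail capture entirely.

Bulk interaction-screen counts and library-design candidate tables are
simulated by the same module.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .core_stats import CountMatrix
from .interaction import ScreenCounts
from .manifest import NTC, LibraryManifest

__all__ = [
    "StateSpec",
    "CaptureNoise",
    "ExpressionModel",
    "GroundTruth",
    "SimulatedScreen",
    "simulate_screen",
    "simulate_interaction_screen",
    "simulate_candidate_tables",
    "make_modular_truth",
]


@dataclass(frozen=True)
class StateSpec:
    """One cell state: prevalence plus fold multipliers on marker genes."""

    name: str
    prevalence: float
    marker_multipliers: Mapping[str, float] = field(default_factory=dict)


@dataclass(frozen=True)
class CaptureNoise:
    lambda_true: float = 15.0
    lambda_background: float = 0.005
    doublet_rate: float = 0.05
    unassigned_rate: float = 0.10

    def __post_init__(self) -> None:
        for name in ("doublet_rate", "unassigned_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.lambda_true < 0 or self.lambda_background < 0:
            raise ValueError("capture rates must be non-negative")


@dataclass(frozen=True)
class ExpressionModel:
    """Negative-binomial expression with lognormal library-size factors."""

    baseline_mean: Mapping[str, float]  # per-gene μ_g at library factor 1
    dispersion: float = 2.0  # NB size θ; var = μ + μ²/θ
    libsize_sigma: float = 0.3
    dead_cell_rate: float = 0.0  # cells with inflated mitochondrial load
    dead_mito_factor: float = 8.0
    mito_prefix: str = "mt-"

    def __post_init__(self) -> None:
        if any(m <= 0 for m in self.baseline_mean.values()):
            raise ValueError("baseline means must be positive")
        if self.dispersion <= 0:
            raise ValueError("dispersion must be positive")
        if not 0.0 <= self.dead_cell_rate <= 1.0:
            raise ValueError("dead_cell_rate must be in [0, 1]")


@dataclass
class GroundTruth:
    """Planted structure driving one simulated screen."""

    tf_modules: dict[str, list[str]]  # partition of gene-level targets
    gene_programmes: dict[str, list[str]]  # partition of the effect gene panel
    effect_matrix_E: pd.DataFrame  # modules × programmes, log2 effects
    states: list[StateSpec]
    abundance_profile: dict[str, float]  # target (incl NTC) -> weight
    capture_noise: CaptureNoise = field(default_factory=CaptureNoise)
    expression_model: ExpressionModel = field(
        default_factory=lambda: ExpressionModel({"G1": 1.0})
    )

    def __post_init__(self) -> None:
        _check_partition(self.tf_modules, "tf_modules")
        _check_partition(self.gene_programmes, "gene_programmes")
        prev = sum(s.prevalence for s in self.states)
        if self.states and abs(prev - 1.0) > 1e-8:
            raise ValueError(f"state prevalences sum to {prev}, expected 1")
        if any(w < 0 for w in self.abundance_profile.values()):
            raise ValueError("abundance weights must be non-negative")
        E = self.effect_matrix_E
        if list(E.index) != list(self.tf_modules) or list(E.columns) != list(
            self.gene_programmes
        ):
            raise ValueError("effect_matrix_E axes must match module/programme names")

    @property
    def module_of_target(self) -> dict[str, str]:
        return {t: m for m, ts in self.tf_modules.items() for t in ts}

    @property
    def programme_of_gene(self) -> dict[str, str]:
        return {g: p for p, gs in self.gene_programmes.items() for g in gs}


def _check_partition(parts: Mapping[str, Sequence[str]], what: str) -> None:
    seen: set[str] = set()
    for name, members in parts.items():
        for m in members:
            if m in seen:
                raise ValueError(f"{what}: {m!r} appears in more than one block")
            seen.add(m)


@dataclass
class SimulatedScreen:
    expression: CountMatrix
    sgrna_counts: CountMatrix
    true_assignment: pd.DataFrame  # cell_id, target, construct_id, second_target, singlet, captured
    true_state: pd.Series  # cell_id -> state name
    truth: GroundTruth
    seed: int


def _target_effect_multipliers(
    truth: GroundTruth, targets: list[str], genes: list[str]
) -> np.ndarray:
    """T × G matrix of 2^{E[module(t), programme(g)]} (1 where no effect)."""
    mod_of = truth.module_of_target
    prog_of = truth.programme_of_gene
    E = truth.effect_matrix_E
    out = np.ones((len(targets), len(genes)))
    for i, t in enumerate(targets):
        mod = mod_of.get(t)
        if mod is None or t == NTC:
            continue
        for j, g in enumerate(genes):
            prog = prog_of.get(g)
            if prog is not None:
                out[i, j] = 2.0 ** E.loc[mod, prog]
    return out


def _state_multipliers(
    states: list[StateSpec], genes: list[str]
) -> np.ndarray:
    out = np.ones((max(len(states), 1), len(genes)))
    gene_idx = {g: j for j, g in enumerate(genes)}
    for i, s in enumerate(states):
        for g, mult in s.marker_multipliers.items():
            j = gene_idx.get(g)
            if j is not None:
                out[i, j] = mult
    return out


def simulate_screen(
    truth: GroundTruth,
    manifest: LibraryManifest,
    n_cells: int,
    seed: int,
) -> SimulatedScreen:
    """Draw one screen (expression + sgRNA capture) from the planted truth."""
    if n_cells <= 0:
        raise ValueError("n_cells must be positive")
    targets = manifest.targets
    unknown = set(truth.abundance_profile) - set(targets)
    if unknown:
        raise ValueError(
            f"abundance profile names targets absent from the manifest: {sorted(unknown)}"
        )
    missing = [t for t in targets if t not in truth.abundance_profile]
    if missing:
        raise ValueError(f"abundance profile missing targets: {missing[:5]}")

    rng = np.random.default_rng(seed)
    genes = list(truth.expression_model.baseline_mean)
    mu = np.array([truth.expression_model.baseline_mean[g] for g in genes])
    theta = truth.expression_model.dispersion
    noise = truth.capture_noise

    # --- per-cell latent draws -------------------------------------------
    weights = np.array([truth.abundance_profile[t] for t in targets], dtype=float)
    weights = weights / weights.sum()
    target_idx = rng.choice(len(targets), size=n_cells, p=weights)

    if truth.states:
        prev = np.array([s.prevalence for s in truth.states])
        state_idx = rng.choice(len(truth.states), size=n_cells, p=prev)
        state_names = [s.name for s in truth.states]
    else:
        state_idx = np.zeros(n_cells, dtype=int)
        state_names = ["state0"]

    cons_by_target: dict[str, list[int]] = {t: [] for t in targets}
    for ci, con in enumerate(manifest.constructs):
        cons_by_target[con.target].append(ci)
    construct_idx = np.array(
        [rng.choice(cons_by_target[targets[t]]) for t in target_idx]
    )

    is_doublet = rng.random(n_cells) < noise.doublet_rate
    second_construct = np.full(n_cells, -1)
    n_cons = len(manifest.constructs)
    second_construct[is_doublet] = rng.integers(0, n_cons, size=int(is_doublet.sum()))
    captured = rng.random(n_cells) >= noise.unassigned_rate
    libsize = rng.lognormal(0.0, truth.expression_model.libsize_sigma, size=n_cells)
    dead = rng.random(n_cells) < truth.expression_model.dead_cell_rate

    # --- expression -------------------------------------------------------
    tmult = _target_effect_multipliers(truth, targets, genes)
    smult = _state_multipliers(truth.states, genes)
    mean = libsize[:, None] * mu[None, :] * tmult[target_idx] * smult[state_idx]
    con_targets = [c.target for c in manifest.constructs]
    if is_doublet.any():
        second_tidx = np.array(
            [targets.index(con_targets[c]) if c >= 0 else 0 for c in second_construct]
        )
        mean[is_doublet] *= tmult[second_tidx[is_doublet]]
    mito_mask = np.array(
        [g.startswith(truth.expression_model.mito_prefix) for g in genes]
    )
    if dead.any() and mito_mask.any():
        mean[np.ix_(dead, mito_mask)] *= truth.expression_model.dead_mito_factor
    counts = rng.poisson(rng.gamma(theta, mean / theta))

    cell_ids = [f"cell{idx:05d}" for idx in range(n_cells)]
    expression = CountMatrix(
        sp.csr_matrix(counts), cell_ids, genes, feature_kind="gene"
    )

    # --- sgRNA capture ----------------------------------------------------
    guide_ids = [g.guide_id for g in manifest.guides]
    guide_pos = {g: i for i, g in enumerate(guide_ids)}
    con_guides = [
        (guide_pos[c.guide_a.guide_id], guide_pos[c.guide_b.guide_id])
        for c in manifest.constructs
    ]
    n_guides = len(guide_ids)
    sg = sp.lil_matrix((n_cells, n_guides), dtype=np.int64)

    # true-construct molecules
    for cell in range(n_cells):
        if not captured[cell]:
            continue
        for ci in [construct_idx[cell]] + (
            [second_construct[cell]] if is_doublet[cell] else []
        ):
            for gpos in con_guides[ci]:
                c = rng.poisson(noise.lambda_true)
                if c:
                    sg[cell, gpos] += c
    # ambient background: total per cell ~ Poisson(G·λ_b), uniform over guides
    if noise.lambda_background > 0:
        bg_totals = rng.poisson(n_guides * noise.lambda_background, size=n_cells)
        for cell in np.nonzero(bg_totals)[0]:
            for gpos in rng.integers(0, n_guides, size=bg_totals[cell]):
                sg[cell, gpos] += 1

    sgrna_counts = CountMatrix(
        sp.csr_matrix(sg), cell_ids, guide_ids, feature_kind="sgRNA"
    )

    second_target = np.where(
        is_doublet,
        [con_targets[c] if c >= 0 else "" for c in second_construct],
        "",
    )
    primary_target = np.array([targets[t] for t in target_idx])
    singlet = (~is_doublet) | (second_target == primary_target)
    assignment = pd.DataFrame(
        {
            "cell_id": cell_ids,
            "target": primary_target,
            "construct_id": [
                manifest.constructs[c].construct_id for c in construct_idx
            ],
            "second_target": second_target,
            "singlet": singlet,
            "captured": captured,
        }
    ).set_index("cell_id", drop=False)
    true_state = pd.Series(
        [state_names[i] for i in state_idx], index=cell_ids, name="state"
    )
    return SimulatedScreen(
        expression=expression,
        sgrna_counts=sgrna_counts,
        true_assignment=assignment,
        true_state=true_state,
        truth=truth,
        seed=seed,
    )


def simulate_interaction_screen(
    gene_effects: pd.DataFrame,
    manifest: LibraryManifest,
    depth: int,
    seed: int,
    sample_meta: pd.DataFrame | None = None,
    guide_skew_sigma: float = 0.25,
) -> ScreenCounts:
    """Simulate sgRNA × sample counts for a bulk interaction screen.

    ``gene_effects`` is genes × samples of expected log2 enrichment relative
    to the library baseline (rows may omit genes — treated as 0; NTC is
    always 0 unless listed). Counts per sample are multinomial at the given
    read depth over expected proportions ∝ guide skew × 2^effect.
    """
    if depth <= 0:
        raise ValueError("depth must be positive")
    rng = np.random.default_rng(seed)
    guides = manifest.guides
    guide_ids = [g.guide_id for g in guides]
    gtargets = pd.Series([g.target for g in guides], index=guide_ids)
    base = rng.lognormal(0.0, guide_skew_sigma, size=len(guides))
    samples = list(gene_effects.columns)
    counts = {}
    for s in samples:
        eff = np.array(
            [
                gene_effects.loc[g.target, s]
                if g.target in gene_effects.index
                else 0.0
                for g in guides
            ]
        )
        props = base * np.power(2.0, eff)
        props = props / props.sum()
        counts[s] = rng.multinomial(depth, props)
    df = pd.DataFrame(counts, index=guide_ids)
    if sample_meta is None:
        sample_meta = pd.DataFrame(
            {"arm": ["unspecified"] * len(samples), "compartment": samples},
            index=samples,
        )
    return ScreenCounts(counts=df, sample_meta=sample_meta, guide_targets=gtargets)


def simulate_candidate_tables(
    truth_flags: Mapping[str, pd.DataFrame],
    seed: int,
    strong_lfc: tuple[float, float] = (0.8, 2.0),
    weak_lfc: tuple[float, float] = (0.0, 0.3),
    strong_or: tuple[float, float] = (2.0, 6.0),
    weak_or: tuple[float, float] = (0.6, 1.4),
) -> dict[str, dict[str, pd.DataFrame]]:
    """Fabricate per-dataset DE/DA/ME evidence tables from planted flags.

    ``truth_flags`` maps dataset name -> frame indexed by TF with boolean
    columns ``de``, ``da``, ``me``. In the output, a flagged analysis yields
    evidence passing the library-design thresholds (|lfc| > 0.5 & FDR < 0.05
    for DE/DA; OR > 1.5 & FDR < 0.05 for ME) and an unflagged one does not.
    """
    if not truth_flags:
        raise ValueError("at least one dataset is required")
    rng = np.random.default_rng(seed)
    out: dict[str, dict[str, pd.DataFrame]] = {}
    for ds, flags in truth_flags.items():
        tfs = list(flags.index)
        n = len(tfs)
        tables: dict[str, pd.DataFrame] = {}
        for channel in ("de", "da"):
            on = flags[channel].to_numpy(dtype=bool)
            mag = np.where(
                on,
                rng.uniform(*strong_lfc, size=n),
                rng.uniform(*weak_lfc, size=n),
            )
            sign = rng.choice([-1.0, 1.0], size=n)
            fdr = np.where(
                on,
                rng.uniform(1e-6, 0.01, size=n),
                rng.uniform(0.2, 0.95, size=n),
            )
            tables[channel] = pd.DataFrame(
                {"lfc": sign * mag, "fdr": fdr}, index=pd.Index(tfs, name="tf")
            )
        on = flags["me"].to_numpy(dtype=bool)
        orr = np.where(
            on, rng.uniform(*strong_or, size=n), rng.uniform(*weak_or, size=n)
        )
        fdr = np.where(
            on, rng.uniform(1e-6, 0.01, size=n), rng.uniform(0.2, 0.95, size=n)
        )
        tables["me"] = pd.DataFrame(
            {"odds_ratio": orr, "fdr": fdr}, index=pd.Index(tfs, name="tf")
        )
        out[ds] = tables
    return out


def make_modular_truth(
    targets: Sequence[str],
    n_modules: int,
    genes_per_programme: int,
    n_programmes: int = 4,
    effect_size: float = 1.0,
    extra_genes: Mapping[str, float] | None = None,
    states: Sequence[StateSpec] = (),
    capture_noise: CaptureNoise | None = None,
    dispersion: float = 2.0,
    libsize_sigma: float = 0.3,
    baseline_low: float = 0.5,
    baseline_high: float = 4.0,
    ntc_weight: float | None = None,
    seed: int = 0,
) -> GroundTruth:
    """Build a GroundTruth with K planted modules and P planted programmes.

    Targets are dealt round-robin into modules; each module gets a distinct
    sign pattern over programmes (scaled by ``effect_size``), chosen from a
    fixed catalogue so module signatures are mutually well separated.
    ``extra_genes`` (e.g. markers, mitochondrial genes, housekeeping) join
    the expression model without a programme, hence without effects.
    """
    # Sum-zero sign patterns: every module redirects expression between
    # programmes rather than scaling it globally. A uniform up/down module
    # would be cancelled by per-cell library-size normalization (the
    # compositional shift), making it unidentifiable downstream.
    patterns = [
        (+1, -1, 0, 0),
        (0, 0, +1, -1),
        (+1, 0, -1, 0),
        (0, +1, 0, -1),
        (-1, +1, 0, 0),
        (0, 0, -1, +1),
        (-1, 0, +1, 0),
        (0, -1, 0, +1),
        (+1, +1, -1, -1),
        (-1, -1, +1, +1),
        (+1, -1, +1, -1),
        (-1, +1, -1, +1),
    ]
    if n_modules > len(patterns):
        raise ValueError(f"at most {len(patterns)} planted modules supported")
    if n_programmes > 4:
        raise ValueError("at most 4 planted programmes supported")
    rng = np.random.default_rng(seed)
    module_names = [f"M{i + 1}" for i in range(n_modules)]
    programme_names = [chr(ord("A") + i) for i in range(n_programmes)]
    tf_modules: dict[str, list[str]] = {m: [] for m in module_names}
    for i, t in enumerate(targets):
        tf_modules[module_names[i % n_modules]].append(t)
    gene_programmes = {
        p: [f"{p}{j + 1:03d}" for j in range(genes_per_programme)]
        for p in programme_names
    }
    E = pd.DataFrame(
        [
            [effect_size * patterns[k][q] for q in range(n_programmes)]
            for k in range(n_modules)
        ],
        index=module_names,
        columns=programme_names,
    )
    baseline: dict[str, float] = {}
    for p in programme_names:
        for g in gene_programmes[p]:
            baseline[g] = float(rng.uniform(baseline_low, baseline_high))
    for g, m in (extra_genes or {}).items():
        baseline[g] = float(m)
    abundance = {t: 1.0 for t in targets}
    abundance[NTC] = float(ntc_weight if ntc_weight is not None else len(targets) / 5)
    return GroundTruth(
        tf_modules=tf_modules,
        gene_programmes=gene_programmes,
        effect_matrix_E=E,
        states=list(states),
        abundance_profile=abundance,
        capture_noise=capture_noise or CaptureNoise(),
        expression_model=ExpressionModel(
            baseline_mean=baseline,
            dispersion=dispersion,
            libsize_sigma=libsize_sigma,
        ),
    )
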