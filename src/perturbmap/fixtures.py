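"""Packaged fixtures: pinned seeds and parameters for reproducible runs.

Three version-controlled fixture configurations ship with the package:

* ``abundance_v1`` — a full-size screen (180 targets, 24,000 cells) whose
  abundance profile plants eight strongly depleted perturbations below the
  minimum-cells filter.
* ``truth_v1`` — a modular screen (9 planted TF modules × 5 targets, 4
  planted programmes × 30 genes) with noiseless capture, for clustering and
  network recovery.
* ``candidates_v1`` — four fabricated evidence datasets driving the TF
  nomination and ranking pipeline to an unambiguous final library.

All fixture randomness is derived from the seeds pinned in the YAML files,
so regeneration is bit-identical.
"""

from __future__ import annotations

from importlib import resources
from typing import Any

import numpy as np
import pandas as pd
import yaml

from .manifest import LibraryManifest, build_manifest
from .synthetic import (
    CaptureNoise,
    ExpressionModel,
    GroundTruth,
    make_modular_truth,
    simulate_candidate_tables,
)

__all__ = [
    "DEFAULT_TF_TARGETS",
    "load_fixture",
    "generate_protospacers",
    "build_library_manifest",
    "abundance_v1",
    "truth_v1",
    "candidates_v1",
]

# The packaged 180-gene target list: exhaustion-associated mouse TF symbols
# padded with synthetic placeholders to the library size.
_NAMED_TFS = [
    "Ikzf1", "Ets1", "Rbpj", "Tcf7", "Tox", "Bach2", "Irf1", "Irf4",
    "Junb", "Klf2", "Stat5a", "Stat5b", "Yy1", "Zbtb32", "Ezh2", "Nr4a1",
    "Nr4a2", "Nr4a3", "Fli1", "Runx1", "Runx2", "Runx3", "Jun", "Batf",
    "Tbx21", "Eomes", "Prdm1", "Id2", "Id3", "Foxo1", "Bcl6", "Myb",
    "Myc", "Klf4", "Egr1", "Egr2", "Ikzf2", "Ikzf3", "Satb1", "Zeb2",
]
DEFAULT_TF_TARGETS: list[str] = _NAMED_TFS + [
    f"Tf{i:03d}" for i in range(41, 181)
]


def load_fixture(name: str) -> dict[str, Any]:
    """Load one packaged fixture configuration by name."""
    path = resources.files("perturbmap") / "fixtures" / f"{name}.yaml"
    with path.open() as fh:
        return yaml.safe_load(fh)


def generate_protospacers(n: int, seed: int, length: int = 20) -> list[str]:
    """Deterministic unique random protospacers (ACGT alphabet)."""
    rng = np.random.default_rng(seed)
    out: list[str] = []
    seen: set[str] = set()
    bases = np.array(list("ACGT"))
    while len(out) < n:
        s = "".join(bases[rng.integers(0, 4, size=length)])
        if s not in seen:
            seen.add(s)
            out.append(s)
    return out


def build_library_manifest(
    targets: list[str] | None = None,
    seed: int = 7,
    guides_per_gene: int = 4,
    ntc_constructs: int = 40,
) -> LibraryManifest:
    """The dual-guide library over the packaged (or given) target list."""
    targets = list(targets if targets is not None else DEFAULT_TF_TARGETS)
    n_gene_spacers = len(targets) * guides_per_gene
    n_ntc_spacers = ntc_constructs * 2
    spacers = generate_protospacers(n_gene_spacers + n_ntc_spacers, seed)
    guide_source = {
        t: spacers[i * guides_per_gene : (i + 1) * guides_per_gene]
        for i, t in enumerate(targets)
    }
    return build_manifest(
        targets,
        guide_source,
        guides_per_gene=guides_per_gene,
        ntc_constructs=ntc_constructs,
        ntc_protospacers=spacers[n_gene_spacers:],
    )


def abundance_v1() -> dict[str, Any]:
    """Ground truth + manifest for the perturbation-retention fixture."""
    cfg = load_fixture("abundance_v1")
    manifest = build_library_manifest(seed=cfg["library_seed"])
    targets = manifest.gene_targets
    depleted = set(cfg["depleted_targets"])
    missing = depleted - set(targets)
    if missing:
        raise ValueError(f"depleted targets not in library: {sorted(missing)}")
    abundance = {t: (cfg["depleted_weight"] if t in depleted else 1.0) for t in targets}
    abundance["NTC"] = float(cfg["ntc_weight"])

    expr_cfg = cfg["expression"]
    rng = np.random.default_rng(1000 + cfg["seed"])
    baseline: dict[str, float] = {}
    for i in range(expr_cfg["n_background_genes"]):
        baseline[f"Bg{i + 1:03d}"] = float(
            rng.uniform(expr_cfg["background_mean_low"], expr_cfg["background_mean_high"])
        )
    for g in expr_cfg["mito_genes"]:
        baseline[g] = float(expr_cfg["mito_mean"])

    truth = GroundTruth(
        tf_modules={"M1": targets},
        gene_programmes={},
        effect_matrix_E=pd.DataFrame(index=["M1"], columns=[], dtype=float),
        states=[],
        abundance_profile=abundance,
        capture_noise=CaptureNoise(**cfg["capture_noise"]),
        expression_model=ExpressionModel(
            baseline_mean=baseline,
            dispersion=expr_cfg["dispersion"],
            libsize_sigma=expr_cfg["libsize_sigma"],
            dead_cell_rate=expr_cfg["dead_cell_rate"],
            dead_mito_factor=expr_cfg["dead_mito_factor"],
        ),
    )
    return {
        "truth": truth,
        "manifest": manifest,
        "n_cells": cfg["n_cells"],
        "seed": cfg["seed"],
        "min_cells": cfg["min_cells"],
        "depleted_targets": sorted(depleted),
    }


def truth_v1() -> dict[str, Any]:
    """Ground truth + manifest for the module/programme recovery fixture."""
    cfg = load_fixture("truth_v1")
    n_targets = cfg["n_modules"] * cfg["targets_per_module"]
    targets = DEFAULT_TF_TARGETS[:n_targets]
    manifest = build_library_manifest(
        targets=targets, seed=cfg["library_seed"], ntc_constructs=10
    )
    truth = make_modular_truth(
        targets,
        n_modules=cfg["n_modules"],
        genes_per_programme=cfg["genes_per_programme"],
        n_programmes=cfg["n_programmes"],
        effect_size=cfg["effect_size"],
        capture_noise=CaptureNoise(**cfg["capture_noise"]),
        dispersion=cfg["dispersion"],
        libsize_sigma=cfg["libsize_sigma"],
        baseline_low=cfg["baseline_low"],
        baseline_high=cfg["baseline_high"],
        ntc_weight=cfg["ntc_weight"],
        seed=500 + cfg["library_seed"],
    )
    return {
        "truth": truth,
        "manifest": manifest,
        "n_cells": cfg["n_cells"],
        "seeds": list(cfg["seeds"]),
        "min_cells": cfg["min_cells"],
    }


def candidates_v1() -> dict[str, Any]:
    """Evidence tables + composition config for the nomination fixture.

    Every library target except the curated nine is nominated (2-of-3
    channels) in at least one dataset; the curated nine and the extra
    non-library TFs never reach two channels in any dataset, so the final
    list is exactly the ranked component plus the curated additions.
    """
    cfg = load_fixture("candidates_v1")
    curated = list(cfg["curated"])
    datasets = list(cfg["datasets"])
    extras = [f"Zfp{i:03d}" for i in range(1, cfg["n_extra_tfs"] + 1)]
    universe = DEFAULT_TF_TARGETS + extras
    nominated = [t for t in DEFAULT_TF_TARGETS if t not in curated]
    tiers = cfg["nomination_tiers"]
    tier_sizes = [tiers["four"], tiers["three"], tiers["two"], tiers["one"]]
    tier_noms = [4, 3, 2, 1]
    if sum(tier_sizes) != len(nominated):
        raise ValueError("nomination tiers do not cover the nominated TFs")

    rng = np.random.default_rng(cfg["seed"])
    flags = {
        ds: pd.DataFrame(
            False,
            index=pd.Index(universe, name="tf"),
            columns=["de", "da", "me"],
        )
        for ds in datasets
    }
    channels = np.array(["de", "da", "me"])
    pos = 0
    for size, n_noms in zip(tier_sizes, tier_noms):
        for tf in nominated[pos : pos + size]:
            ds_pick = rng.choice(len(datasets), size=n_noms, replace=False)
            for d in ds_pick:
                n_ch = int(rng.integers(2, 4))  # 2 or 3 channels
                for ch in rng.choice(channels, size=n_ch, replace=False):
                    flags[datasets[d]].loc[tf, ch] = True
        pos += size
    # background single-channel evidence for never-nominated TFs
    for tf in curated + extras:
        for ds in datasets:
            if rng.random() < 0.3:
                flags[ds].loc[tf, str(rng.choice(channels))] = True

    tables = simulate_candidate_tables(flags, seed=cfg["seed"] + 1)
    return {
        "dataset_tables": tables,
        "truth_flags": flags,
        "top_n": int(cfg["top_n"]),
        "curated": curated,
        "universe": universe,
    }
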