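"""Shared fixtures: small manifests and session-scoped simulated screens."""

from __future__ import annotations

import warnings

import numpy as np
import pytest

from perturbmap.assignment import assign_cells, call_guides, qc_filter
from perturbmap.core_stats import log_normalize
from perturbmap.de import perturbation_de
from perturbmap.fixtures import (
    abundance_v1,
    build_library_manifest,
    truth_v1,
)
from perturbmap.manifest import NTC
from perturbmap.regmap import build_effect_matrix
from perturbmap.synthetic import (
    CaptureNoise,
    make_modular_truth,
    simulate_screen,
)


@pytest.fixture(scope="session")
def small_manifest():
    """Six genes, four guides each, four NTC constructs."""
    return build_library_manifest(
        targets=[f"Gene{i}" for i in range(1, 7)], seed=3, ntc_constructs=4
    )


@pytest.fixture(scope="session")
def abundance_run():
    """The packaged abundance_v1 screen taken through QC and assignment."""
    fx = abundance_v1()
    screen = simulate_screen(fx["truth"], fx["manifest"], fx["n_cells"], fx["seed"])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        kept, qc = qc_filter(screen.expression)
        sg = screen.sgrna_counts.subset_cells(kept)
        assignment = assign_cells(call_guides(sg), fx["manifest"])
    return {"fixture": fx, "screen": screen, "kept": kept, "qc": qc,
            "assignment": assignment}


def run_truth_v1_seed(seed: int):
    """One truth_v1 replicate through DE to the effect matrix."""
    fx = truth_v1()
    screen = simulate_screen(fx["truth"], fx["manifest"], fx["n_cells"], seed)
    assignment = assign_cells(call_guides(screen.sgrna_counts), fx["manifest"])
    norm = log_normalize(screen.expression)
    de = {
        t: perturbation_de(norm, assignment, t, min_cells=fx["min_cells"])
        for t in fx["manifest"].gene_targets
    }
    E = build_effect_matrix(de, list(norm.gene_ids))
    return {"fixture": fx, "truth": fx["truth"], "screen": screen,
            "assignment": assignment, "norm": norm, "de": de, "E": E}


@pytest.fixture(scope="session")
def truthv1_run():
    """First-seed truth_v1 replicate, shared by map-stage tests."""
    return run_truth_v1_seed(truth_v1()["seeds"][0])


@pytest.fixture(scope="session")
def recovery_screens():
    """Two small screens for DE calibration: planted ±0.8 effect and null.

    Two gene-level targets plus NTC at equal abundance over 2,000 cells
    gives ≈660 singlets per group — at least 500 cells on each side of the
    DE comparison. The planted truth uses a single module with the
    (+1, −1, 0, 0) programme pattern at effect size 0.8.
    """
    noiseless = CaptureNoise(
        lambda_true=15.0, lambda_background=0.0, doublet_rate=0.0, unassigned_rate=0.0
    )
    # unaffected background transcriptome: keeps the programme effects a
    # small fraction of each cell's library, as in real data, so per-cell
    # normalization does not fold the effect back into every gene
    bg_rng = np.random.default_rng(99)
    background = {
        f"Hk{i:03d}": float(m) for i, m in enumerate(bg_rng.uniform(1, 4, 150))
    }
    out = {}
    for name, effect in (("planted", 0.8), ("null", 0.0)):
        truth = make_modular_truth(
            ["TargetA", "TargetB"],
            n_modules=1,
            genes_per_programme=25,
            n_programmes=4,
            effect_size=effect,
            extra_genes=background,
            capture_noise=noiseless,
            ntc_weight=1.0,
            seed=42,
        )
        manifest = build_library_manifest(
            targets=["TargetA", "TargetB"], seed=13, ntc_constructs=4
        )
        screen = simulate_screen(truth, manifest, 2000, seed=77)
        assignment = assign_cells(call_guides(screen.sgrna_counts), manifest)
        norm = log_normalize(screen.expression)
        de = perturbation_de(norm, assignment, "TargetA", min_cells=48)
        out[name] = {"truth": truth, "de": de, "norm": norm,
                     "assignment": assignment}
    return out
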