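import logging
import warnings

import numpy as np
import pytest

from tracemap.cellmap import solve_depth
from tracemap.normalize import NormalizationConfig
from tracemap.phantom import (
    PhantomConfig,
    make_template,
    plant_cells,
    slice_and_distort,
    slice_volume_with_chain,
)
from tracemap.pipeline import evaluate_against_truth, map_cells_for_case, run_case
from tracemap.reconstruct import ReconstructionConfig

logging.getLogger("tracemap").setLevel(logging.ERROR)
warnings.filterwarnings("ignore", message="constant image")


@pytest.fixture(scope="session")
def small_cfg():
    """A reduced shell phantom for module-level registration tests."""
    return PhantomConfig(
        grid_size=48,
        inner_radius_mm=3.2,
        outer_radius_mm=4.4,
        n_cells_per_injection=200,
        seed=77,
    )


@pytest.fixture(scope="session")
def small_template(small_cfg):
    return make_template(small_cfg)


@pytest.fixture(scope="session")
def default_cfg():
    """The default phantom study conditions."""
    return PhantomConfig()


@pytest.fixture(scope="session")
def default_phantom(default_cfg):
    intensity, labels, landmarks = make_template(default_cfg)
    stack, chain, mask = slice_and_distort(intensity, default_cfg, labels)
    lm_stack = slice_volume_with_chain(
        landmarks, chain, stack.section_geometry(), len(stack), interp="nearest"
    )
    cells, truth = plant_cells(labels, chain, default_cfg)
    return {
        "cfg": default_cfg,
        "intensity": intensity,
        "labels": labels,
        "landmarks": landmarks,
        "stack": stack,
        "gt_chain": chain,
        "mask": mask,
        "landmark_stack": lm_stack,
        "cells": cells,
        "truth": truth,
    }


@pytest.fixture(scope="session")
def default_run(default_phantom):
    """Full pipeline on the default phantom (the heavyweight fixture)."""
    ph = default_phantom
    result = run_case(
        ph["stack"],
        ph["intensity"],
        ph["labels"],
        ph["landmarks"],
        ph["landmark_stack"],
        ReconstructionConfig(),
        NormalizationConfig(working_resolution_mm=ph["cfg"].spacing_mm),
    )
    depth = solve_depth(ph["labels"])
    records = map_cells_for_case(
        ph["cells"], result.chain, ph["labels"], depth, shell_center=ph["cfg"].center
    )
    stats = evaluate_against_truth(records, ph["truth"], injected_area=1)
    return {"result": result, "depth": depth, "records": records, "stats": stats}
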