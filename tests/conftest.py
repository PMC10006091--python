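import time

import numpy as np
import pytest

import vmatqa as vq
from vmatqa.pipeline import StudyConfig, run_study


@pytest.fixture(scope="session")
def d729():
    return vq.build_array("d729")


@pytest.fixture(scope="session")
def d1500():
    return vq.build_array("d1500")


@pytest.fixture(scope="session")
def beam():
    return vq.make_beam_model()


@pytest.fixture(scope="session")
def flat_tpr_beam():
    """Beam whose PDD is pure inverse-square falloff, so TPR is 1 everywhere."""
    return vq.make_beam_model(
        pdd_fn=lambda d: ((900.0 + 15.0) / (900.0 + np.asarray(d, dtype=float))) ** 2
    )


def open_square_spec(
    half_mm: float = 50.0, penumbra_mm: float = 0.0, weight: float = 1.0
) -> vq.FieldSpec:
    """A single fully open square field of side 2*half_mm."""
    widths = vq.hd120_leaf_widths()
    edges = np.concatenate([[0.0], np.cumsum(widths)]) - widths.sum() / 2
    centers = 0.5 * (edges[:-1] + edges[1:])
    openings = np.zeros((widths.size, 2))
    inside = (edges[:-1] >= -half_mm - 1e-9) & (edges[1:] <= half_mm + 1e-9)
    openings[inside] = (-half_mm, half_mm)
    return vq.FieldSpec(
        segments=[vq.Segment(openings=openings, weight=weight)],
        penumbra_mm=penumbra_mm,
        collimator_deg=0.0,
    )


@pytest.fixture(scope="session")
def modulated_dose():
    """A deterministic modulated VMAT-like planar dose (1 mm grid)."""
    rng = np.random.default_rng(2024)
    spec = vq.random_field_spec(rng, collimator_deg=0.0)
    return vq.generate_vmat_dosemap(spec, 0)


@pytest.fixture(scope="session")
def full_study(tmp_path_factory):
    """The complete seeded QA study at its default cohort sizes.

    Shared across tests so the most expensive simulation runs once; the
    elapsed wall time is returned alongside the result.
    """
    out = tmp_path_factory.mktemp("study")
    cfg = StudyConfig(seed=1, output_dir=str(out), figures=False)
    t0 = time.monotonic()
    result = run_study(cfg)
    elapsed = time.monotonic() - t0
    return result, elapsed
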