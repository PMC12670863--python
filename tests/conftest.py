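import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from cmrcompare.annotation import CaseAnnotation, Contour, ImageGeometry, SliceAnnotation
from cmrcompare.phantom import PhantomParams, Perturbation, generate_case, perturb_reader

settings.register_profile(
    "ci", derandomize=True, deadline=None, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("ci")

UNIT_GEOM = ImageGeometry(spacing_row=1.0, spacing_col=1.0, slice_thickness=8.0, slice_gap=2.0)


def square(x0, y0, side):
    return np.array(
        [[x0, y0], [x0 + side, y0], [x0 + side, y0 + side], [x0, y0 + side]], float
    )


def circle(cx, cy, r, n=360):
    th = np.linspace(0, 2 * np.pi, n, endpoint=False)
    return np.column_stack([cx + r * np.cos(th), cy + r * np.sin(th)])


def make_case(slices, case_id="c1", reader_id="r1", sequence="sax_cine", geom=UNIT_GEOM):
    return CaseAnnotation(case_id, reader_id, sequence, geom, slices)


def slice_with(ctype_points, slice_index=0, phase="ED", value_map=None):
    """Build a SliceAnnotation from {ctype: [points_array, ...]}."""
    contours = {
        ct: [Contour(ct, pts) for pts in plist] for ct, plist in ctype_points.items()
    }
    return SliceAnnotation(slice_index, phase, contours, value_map=value_map)


@pytest.fixture(scope="session")
def cine_pair():
    """A clean cine phantom and a mildly perturbed second reader."""
    r1, truth = generate_case(PhantomParams(), seed=7)
    pert = Perturbation(radial_sigma=0.3, dilation_mm={"lv_endo": 0.5}, seed=11)
    return r1, perturb_reader(r1, pert), truth


@pytest.fixture(scope="session")
def small_params():
    """A reduced phantom for cohort-level tests (keeps suites fast)."""
    return PhantomParams(n_slices=4, n_vertices=120)
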