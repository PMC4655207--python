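import numpy as np
import pytest

import perfseg as ps


def circle_contour(r, center=(32.0, 32.0), n=96, slice_index=0, slice_position=0.0):
    ang = np.linspace(-np.pi, np.pi, n, endpoint=False)
    verts = np.column_stack(
        [center[0] + r * np.cos(ang), center[1] - r * np.sin(ang)]
    )
    return ps.Contour(verts, slice_index, slice_position)


def ellipse_contour(a, b, center=(32.0, 32.0), n=128, slice_index=0, slice_position=0.0):
    ang = np.linspace(-np.pi, np.pi, n, endpoint=False)
    verts = np.column_stack(
        [center[0] + a * np.cos(ang), center[1] - b * np.sin(ang)]
    )
    return ps.Contour(verts, slice_index, slice_position)


@pytest.fixture(scope="session")
def default_cfg():
    return ps.CohortConfig(seed=20240901)


@pytest.fixture(scope="session")
def hcm_subject(default_cfg):
    return ps.generate_subject("hcm", default_cfg, seed=123, subject_id="hcm_fix")


@pytest.fixture(scope="session")
def control_subject(default_cfg):
    return ps.generate_subject("control", default_cfg, seed=321,
                               subject_id="control_fix")


@pytest.fixture(scope="session")
def hcm_fit(hcm_subject):
    return ps.SubjectPerfusionModel(hcm_subject).fit()


@pytest.fixture(scope="session")
def std_aif():
    t = np.arange(60.0)
    return ps.generate_aif_curve(ps.KineticParams(), t, baseline=0.1)
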