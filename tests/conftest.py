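import numpy as np
import pytest

from pteromorph.template import Curve, LandmarkTemplate, pteromyini_template, template_mean_shape


@pytest.fixture(scope="session")
def cranial_template():
    return pteromyini_template()


@pytest.fixture(scope="session")
def cranial_mean(cranial_template):
    return template_mean_shape(cranial_template)


@pytest.fixture
def mini_template():
    """A small digitization scheme: 5 landmarks, one open and one closed
    curve, midline landmarks 0 and 4.  Keeps oracle tests cheap."""
    return LandmarkTemplate(
        n_landmarks=5,
        curves=(
            Curve(start=1, end=2, n_semilandmarks=3),
            Curve(start=None, end=None, n_semilandmarks=6, closed=True),
        ),
        midline=frozenset({0, 4}),
    )


@pytest.fixture
def mini_shape(mini_template):
    """A non-degenerate configuration matching ``mini_template``."""
    lms = np.array([[0.0, 1.0], [0.6, 0.7], [0.8, -0.4], [0.4, -0.8], [0.0, -1.0]])
    t = np.linspace(0, 1, 5)[1:-1, None]
    open_curve = (1 - t) * lms[1] + t * lms[2] + 0.15 * np.column_stack([t[:, 0] * 0 + 1, t[:, 0]])
    ang = np.linspace(0, 2 * np.pi, 7)[:-1]
    closed = np.column_stack([0.35 + 0.12 * np.cos(ang), 0.2 + 0.18 * np.sin(ang)])
    return np.vstack([lms, open_curve, closed])


def rotate(points, theta):
    R = np.array([[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]])
    return points @ R.T
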