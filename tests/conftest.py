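import numpy as np
import pytest

import fluotrack as ft


@pytest.fixture(scope="session")
def small_scene():
    """A small rendered single-blob helix scene shared across tests.

    60 frames at 120x160 keeps the suite fast while exercising the full
    render -> detect -> pair -> triangulate chain.
    """
    cfg = ft.SceneConfig(n_frames=60, image_height=120, image_width=160, random_seed=7)
    cams = ft.default_cameras(cfg)
    traj = ft.make_trajectory("helix", cfg)
    seq1, seq2, truth = ft.render_sequence([traj], cams, cfg)
    return {
        "config": cfg,
        "cameras": cams,
        "trajectory": traj,
        "sequences": (seq1, seq2),
        "truth": truth,
    }


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def random_camera_pair(rng):
    """Two random well-conditioned cameras looking at the origin region."""

    def _make(seed):
        r = np.random.default_rng(seed)
        cams = []
        for i in range(2):
            angle = r.uniform(0, 2 * np.pi)
            center = np.array(
                [50 * np.cos(angle), 50 * np.sin(angle), r.uniform(-10, 10)]
            )
            from fluotrack.synthetic_scene import look_at_rotation

            R = look_at_rotation(center, np.zeros(3))
            cams.append(
                ft.make_camera(
                    r.uniform(200, 600), (r.uniform(100, 200), r.uniform(100, 200)),
                    R, center, view_id=i + 1,
                )
            )
        return cams

    return _make
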