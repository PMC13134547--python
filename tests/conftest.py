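import numpy as np
import pytest

import turnkin as tk


@pytest.fixture(scope="session")
def profile():
    return tk.bluegill_profile()


@pytest.fixture(scope="session")
def uniform_profile():
    """Uniform-cross-section body: constant w = h = 1 cm over 10 cm, rho = 1."""
    s = np.linspace(0.0, 10.0, 11)
    return tk.MorphometricProfile(
        arclengths=s,
        widths=np.ones(11),
        heights=np.ones(11),
        landmark_arclengths=np.linspace(0.0, 10.0, 7),
        density=1.0,
        total_mass=10.0 * np.pi,
        body_length=10.0,
    )


@pytest.fixture(scope="session")
def fast_noiseless(profile):
    spec = tk.fast_turn_spec()
    track, truth = tk.generate_bending_turn(spec)
    return spec, track, truth


@pytest.fixture(scope="session")
def fast_analyzed(fast_noiseless, profile):
    _, track, _ = fast_noiseless
    return tk.analyze_track(track, profile, tk.RunConfig(speed_label="fast"))


def straight_track(n_frames=40, frame_rate=60.0, spacing=1.0, n_points=7, speed=(0.0, 0.0)):
    """Straight horizontal midline, optionally translating; snout at largest x."""
    times = np.arange(n_frames) / frame_rate
    xs = spacing * np.arange(n_points)[::-1]
    pts = np.stack([xs, np.zeros(n_points)], axis=1)
    landmarks = pts[None, :, :] + (np.asarray(speed)[None, :] * times[:, None])[:, None, :]
    return tk.MidlineTrack(
        times=times,
        landmarks=landmarks,
        frame_rate=frame_rate,
        arclengths=spacing * np.arange(n_points),
    )
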