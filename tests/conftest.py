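import numpy as np
import pytest

from adhesionlag import ClusterSpec, SyntheticMovieSpec, generate_movie


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def one_cluster_spec(
    onset_red_s: float = 100.0,
    lag_s: float = 60.0,
    noise=None,
    background=(100.0, (0.0, 0.0)),
    drift=(0.0, 0.0),
    n_frames: int = 60,
    image_shape=(64, 64),
) -> SyntheticMovieSpec:
    """Minimal movie: one elongated cluster on a flat background."""
    cluster = ClusterSpec(
        center=(image_shape[0] / 2, image_shape[1] / 2),
        semi_major_px=4.5,
        semi_minor_px=2.0,
        orientation_rad=0.5,
        onset_red_s=onset_red_s,
        lag_s=lag_s,
    )
    return SyntheticMovieSpec(
        image_shape=image_shape,
        n_frames=n_frames,
        clusters=[cluster],
        noise=noise,
        background=background,
        drift_px_per_frame=drift,
    )


@pytest.fixture()
def one_cluster_movie():
    movie, truth = generate_movie(one_cluster_spec())
    return movie, truth
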