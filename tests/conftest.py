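import numpy as np
import pytest

from trichokit import BinaryFeatureImage, PreprocessParams, SyntheticParams


@pytest.fixture
def default_params() -> PreprocessParams:
    return PreprocessParams()


@pytest.fixture
def clean_synth_params() -> SyntheticParams:
    """Noise-free rendering parameters for exact-truth checks."""
    return SyntheticParams(blur_sigma=0.0, noise_sd=0.0, specular_prob=0.0)


def make_mask(arr: np.ndarray, branch: str = "gls") -> BinaryFeatureImage:
    return BinaryFeatureImage(
        mask=np.asarray(arr, dtype=bool),
        branch=branch,
        erosion_applied=branch != "gls",
    )


def vertical_bar_mask(side: int = 512, col_start: int = 100, width: int = 3, branch: str = "gls") -> BinaryFeatureImage:
    m = np.zeros((side, side), dtype=bool)
    m[:, col_start : col_start + width] = True
    return make_mask(m, branch)


def runs_oracle(line: np.ndarray) -> int:
    """Independent run counter: false->true transitions with a leading False."""
    count, prev = 0, False
    for v in line:
        if v and not prev:
            count += 1
        prev = bool(v)
    return count
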