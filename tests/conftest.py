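import numpy as np
import pytest
from PIL import Image

from histocad.manifest import scan_cmtd_layout
from histocad.synthetic import SyntheticParams, generate_dataset


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def _write_png(path, width, height, value, seed=0):
    r = np.random.default_rng(seed)
    arr = np.clip(value + r.integers(-5, 6, size=(height, width, 3)), 0, 255)
    Image.fromarray(arr.astype(np.uint8), mode="RGB").save(path)


@pytest.fixture
def tiny_cmtd_tree(tmp_path):
    """4 cases (2 per class) x 3 images in the cmtd directory convention."""
    root = tmp_path / "cmtd"
    for label, cid in [("benign", "c1"), ("benign", "c2"),
                       ("malignant", "c3"), ("malignant", "c4")]:
        case = root / f"{label}_{cid}"
        case.mkdir(parents=True)
        for j in range(3):
            _write_png(case / f"img_{j:02d}.png", 80, 70, 128, seed=hash((cid, j)) % 1000)
    return root


@pytest.fixture
def tiny_breakhis_tree(tmp_path):
    """Two patients at 400X (plus one 100X file) in the BreakHis convention."""
    root = tmp_path / "breakhis"
    layout = [
        ("benign", "adenosis", "SOB_B_A_14-22549", "400X", 2),
        ("malignant", "ductal_carcinoma", "SOB_M_DC_14-2523", "400X", 2),
        ("malignant", "ductal_carcinoma", "SOB_M_DC_14-2523", "100X", 1),
    ]
    for label, subtype, patient, mag, n in layout:
        d = root / label / "SOB" / subtype / patient / mag
        d.mkdir(parents=True)
        for j in range(n):
            _write_png(d / f"{patient}-{mag}-{j:03d}.png", 64, 64, 100, seed=j)
    return root


@pytest.fixture(scope="session")
def small_dataset(tmp_path_factory):
    """A small separable synthetic dataset shared by evaluation tests."""
    root = tmp_path_factory.mktemp("smallds")
    params = SyntheticParams(
        n_cases_per_class=6, images_per_case=3, image_size=(96, 96), seed=11
    )
    manifest = generate_dataset(params, root)
    return params, manifest


@pytest.fixture
def rescan(small_dataset):
    _, manifest = small_dataset
    return scan_cmtd_layout(manifest.root)
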