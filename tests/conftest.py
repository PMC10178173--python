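import numpy as np
import pytest
from PIL import Image

from pespyramid import (
    DatasetManifest,
    PhantomSpec,
    RadiographRecord,
    generate_phantoms,
    make_stub_extractor,
)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20231662)


@pytest.fixture(scope="session")
def stub():
    """Small deterministic extractor used throughout the suite."""
    return make_stub_extractor(output_dim=8, seed=7)


@pytest.fixture()
def tiny_manifest():
    """In-memory two-class manifest of small random images."""
    rng = np.random.default_rng(5)
    records = []
    for label, n in (("normal", 3), ("pes_planus", 2)):
        for i in range(n):
            img = rng.integers(0, 256, size=(40, 40, 3), dtype=np.uint8)
            records.append(
                RadiographRecord(image=img, label=label, source_id=f"{label}/{i}")
            )
    return DatasetManifest(records=records)


@pytest.fixture()
def image_dir(tmp_path):
    """On-disk two-class dataset: 3 normal + 3 pes_planus PNGs."""
    rng = np.random.default_rng(11)
    for label in ("normal", "pes_planus"):
        d = tmp_path / label
        d.mkdir()
        for i in range(3):
            arr = rng.integers(0, 256, size=(32, 48, 3), dtype=np.uint8)
            Image.fromarray(arr).save(d / f"img_{i}.png")
    return tmp_path


@pytest.fixture(scope="session")
def small_phantoms():
    """20 separated phantoms at reduced resolution, shared across tests."""
    spec = PhantomSpec(n_per_class=10, side=128, seed=42)
    return generate_phantoms(spec)
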