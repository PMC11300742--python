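import numpy as np
import pytest

from segqa.mask_model import CaseRecord, MaskVolume


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_nested_phantom(shape=(24, 24, 24), center=(12, 12, 12), radii=(3, 5, 8)):
    """Hand-built nested-sphere phantom: label 1 core, 2 shell, 3 outer shell."""
    grids = np.ogrid[tuple(slice(0, s) for s in shape)]
    r2 = sum((g - c) ** 2 for g, c in zip(grids, center))
    labels = np.zeros(shape, dtype=np.int16)
    labels[r2 <= radii[2] ** 2] = 3
    labels[r2 <= radii[1] ** 2] = 2
    labels[r2 <= radii[0] ** 2] = 1
    return MaskVolume.from_voxels(labels)


def make_case(reference, candidate, case_id="c0", status="recurrent", focality="unifocal"):
    return CaseRecord(
        case_id=case_id,
        reference=reference,
        candidate=candidate,
        status=status,
        focality=focality,
    )


@pytest.fixture
def nested_phantom():
    return make_nested_phantom()
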