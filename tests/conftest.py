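import numpy as np
import pytest
from hypothesis import settings

from spatialrqa.patch import ImagePatch
from spatialrqa.texture import PatternClass, TextureSpec, generate_texture_patch

settings.register_profile("suite", derandomize=True, max_examples=25, deadline=None)
settings.load_profile("suite")


@pytest.fixture
def regular_spec():
    return TextureSpec(pattern_class=PatternClass.REGULAR, size_px=64, seed=11)


@pytest.fixture
def regular_patch(regular_spec):
    return generate_texture_patch(regular_spec)


@pytest.fixture
def seeded_patches():
    """20 small patches spanning both phenotype classes, fixed seeds."""
    patches = []
    for i in range(10):
        for cls, jitter in ((PatternClass.REGULAR, 0.05), (PatternClass.IRREGULAR, 0.6)):
            patches.append(
                generate_texture_patch(
                    TextureSpec(pattern_class=cls, size_px=64, jitter=jitter, seed=100 + i)
                )
            )
    return patches


def solid_rgb(r, g, b, side=8):
    px = np.zeros((side, side, 3), dtype=np.uint8)
    px[:, :] = (r, g, b)
    return ImagePatch(pixels=px, mode="RGB", source_id=f"solid-{r}-{g}-{b}")
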