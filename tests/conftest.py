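"""Shared phantom fixtures, session-scoped because generation is the slow part."""

import pytest

import hemovol as hv

#: Standard deep lesion site for the default phantom geometry, (z, y, x) mm.
LESION_CENTER = (55.0, 71.0, 96.0)


@pytest.fixture(scope="session")
def noisy_25cc_phantom():
    """Default-grid (2.5 mm) noisy phantom with a 25 cc spherical bleed and
    both distractors enabled."""
    spec = hv.PhantomSpec(
        lesions=(hv.Lesion(center_mm=LESION_CENTER, semi_axes_mm=hv.sphere_semi_axes(25.0)),),
        falx_plate=True,
        sinus_blob=True,
        seed=42,
    )
    return spec, *hv.generate_phantom(spec)


@pytest.fixture(scope="session")
def noiseless_5mm_phantom():
    """Noiseless phantom on the native 5 mm analysis grid (resampling is a
    no-op), 25 cc lesion, no distractors: truth and analysis grids coincide."""
    spec = hv.PhantomSpec(
        shape=(20, 192, 192),
        spacing=(1.0, 1.0, 5.0),
        neck_slices=2,
        noise_sigma=0.0,
        lesions=(hv.Lesion(center_mm=LESION_CENTER, semi_axes_mm=hv.sphere_semi_axes(25.0)),),
    )
    return spec, *hv.generate_phantom(spec)


@pytest.fixture(scope="session")
def distractor_only_phantom():
    """Lesion-free noisy phantom with falx and sinus distractors enabled."""
    spec = hv.PhantomSpec(falx_plate=True, sinus_blob=True, seed=3)
    return spec, *hv.generate_phantom(spec)
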