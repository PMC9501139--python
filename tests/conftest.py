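import pytest

from spineslip import PhantomSpec, generate_phantom
from spineslip.geometry import SacrumPlate, SpineGeometry, VertebraQuad


@pytest.fixture
def slipped_case():
    """Default-size phantom with a 30% slip at L4-L5."""
    return generate_phantom(
        PhantomSpec(slip_junction="L4L5", slip_fraction=0.3, seed=7)
    )


@pytest.fixture
def clean_case():
    """Noise-free zero-slip phantom."""
    return generate_phantom(PhantomSpec(noise_sd=0.0, seed=3))


def stacked_geometry(
    gap_offsets=(0.0, 0.0, 0.0, 0.0, 0.0),
    width: float = 100.0,
    body_height: float = 40.0,
    gap: float = 12.0,
    x0: float = 50.0,
    y0: float = 20.0,
) -> SpineGeometry:
    """Analytic spine geometry with vertical bodies; ``gap_offsets[m]`` is
    the horizontal displacement accumulated across junction m (so the
    whole stack below shifts, mirroring a slip of the stack above)."""
    geom = SpineGeometry()
    shift = 0.0
    y = y0
    levels = ("L1", "L2", "L3", "L4", "L5")
    for k, level in enumerate(levels):
        geom.quads[level] = VertebraQuad(
            level,
            (x0 + shift, y),
            (x0 + shift + width, y),
            (x0 + shift + width, y + body_height),
            (x0 + shift, y + body_height),
        )
        y += body_height + gap
        shift += gap_offsets[k]
    geom.sacrum = SacrumPlate((x0 + shift, y), (x0 + shift + width, y))
    return geom
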