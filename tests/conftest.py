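import numpy as np
import pytest

from mesoswell import CurveSpec, PhaseSpec, generate_pattern


def noise_scale_for_snr(phase: PhaseSpec, curve: CurveSpec, snr: float,
                        reference: str = "strongest") -> float:
    """noise_scale giving the requested signal-to-noise ratio at a
    reference Bragg peak (the strongest by default; ``"weakest"`` makes the
    condition hold for every reflection of the pattern).

    SNR is peak height above background over the noise sigma at the peak;
    with counting noise sigma = s*sqrt(I_total) this fixes
    s = height / (snr * sqrt(height + background)).
    """
    amps = np.asarray(phase.relative_amplitudes) * phase.amplitude
    i = int(np.argmax(amps)) if reference == "strongest" else int(np.argmin(amps))
    height = float(amps[i])
    bg = float(curve.background(np.array([phase.peak_centers[i]]))[0])
    return height / (snr * np.sqrt(height + bg))


@pytest.fixture
def lamellar_94():
    """Noiseless 3-order lamellar pattern, d = 94 A."""
    return generate_pattern(PhaseSpec("lamellar", 94.0), CurveSpec())


@pytest.fixture
def hexagonal_7255():
    """Noiseless 5-reflection H_II pattern, a = 72.55 A."""
    return generate_pattern(PhaseSpec("hexagonal", 72.55, n_orders=5), CurveSpec())
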