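import numpy as np
import pytest

from glyquant.chem import GlycanComposition, build_library
from glyquant.quantify import build_pair
from glyquant.reference import reference_panel
from glyquant.spectra import PeakList


@pytest.fixture(scope="session")
def panel():
    """The packaged 17-glycan reference panel (ascending theoretical m/z)."""
    return reference_panel()


@pytest.fixture(scope="session")
def default_library():
    """Composition library over the default enumeration ranges."""
    return build_library()


def merge_sticks(mz, amp, tol=0.2):
    """Abundance-weighted merge of stick positions closer than *tol* Da."""
    order = np.argsort(mz)
    mz, amp = np.asarray(mz)[order], np.asarray(amp)[order]
    out_mz, out_amp = [], []
    for m, a in zip(mz, amp):
        if out_mz and m - out_mz[-1] <= tol:
            w = out_amp[-1] + a
            out_mz[-1] = (out_mz[-1] * out_amp[-1] + m * a) / w
            out_amp[-1] = w
        else:
            out_mz.append(float(m))
            out_amp.append(float(a))
    return np.asarray(out_mz), np.asarray(out_amp)


def noise_free_pair_peaklist(comp: GlycanComposition, light: float, heavy: float) -> PeakList:
    """Exact stick spectrum of one light/heavy pair (no noise, no jitter)."""
    pair = build_pair(comp)
    mz = np.concatenate([pair.light.mz, pair.heavy.mz])
    amp = np.concatenate([light * pair.light.abundance, heavy * pair.heavy.abundance])
    mz, amp = merge_sticks(mz, amp)
    return PeakList(mz, amp, amp.copy())
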