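import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

from ggsite.digestion import ModifiedPeptide
from ggsite.fragments import generate_fragments
from ggsite.masscore import mz, peptide_mass
from ggsite.spectra_io import Ms2Spectrum


def ladder_spectrum(
    peptide: ModifiedPeptide,
    precursor_charge: int = 2,
    fragment_charges=(1, 2),
    spectrum_id: str = "test",
    rt: float = 100.0,
    drop=(),
    extra_mz=(),
) -> Ms2Spectrum:
    """Noise-free spectrum containing the peptide's full b/y ladders.

    ``drop`` removes fragments by (series, index); ``extra_mz`` appends
    additional peaks.
    """
    frags = [
        f
        for f in generate_fragments(peptide, fragment_charges)
        if (f.series, f.index) not in drop
    ]
    mzs = [f.mz for f in frags] + list(extra_mz)
    intensities = [100.0] * len(mzs)
    return Ms2Spectrum(
        spectrum_id=spectrum_id,
        precursor_mz=mz(peptide_mass(peptide), precursor_charge),
        precursor_charge=precursor_charge,
        retention_time=rt,
        mz=np.array(mzs),
        intensity=np.array(intensities),
    )


@pytest.fixture
def clean_sim_config():
    from ggsite.synthetic_data import SimConfig

    return SimConfig(
        fragment_dropout_prob=0.0,
        noise_peaks_per_spectrum=0,
        mass_jitter_sd=0.0,
        seed=1,
    )
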