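import pytest

from rmatrace.pair_detection import PeakPair
from rmatrace.peaklist_io import Peak, Role, SampleEntry, SampleTable
from rmatrace.synthetic_data import SimConfig, simulate_peaklist


def make_peak(peak_id, mass, rt, polarity="negative", areas=None):
    return Peak(peak_id, polarity, mass, rt, dict(areas or {}))


def make_pair(parent, partner, **kwargs):
    """Build a PeakPair from two Peak objects with derived diagnostics."""
    defaults = dict(
        parent_id=parent.peak_id,
        partner_id=partner.peak_id,
        parent_mass=parent.neutral_mass,
        partner_mass=partner.neutral_mass,
        parent_rt=parent.rt,
        partner_rt=partner.rt,
        delta_ppm=0.0,
        delta_rt=abs(partner.rt - parent.rt),
        polarity=parent.polarity.value,
    )
    defaults.update(kwargs)
    return PeakPair(**defaults)


@pytest.fixture
def samples_lub():
    """One labeled, one unlabeled control, one blank."""
    return SampleTable([
        SampleEntry("S1", Role.labeled_mix),
        SampleEntry("S2", Role.unlabeled_control),
        SampleEntry("B1", Role.blank),
    ])


@pytest.fixture
def samples_multi():
    """Four labeled + two control samples for correlation-based rules."""
    entries = [SampleEntry(f"L{i}", Role.labeled_mix) for i in range(1, 5)]
    entries += [SampleEntry(f"U{i}", Role.unlabeled_control) for i in range(1, 3)]
    return SampleTable(entries)


@pytest.fixture(scope="session")
def sim_small():
    """A modest simulated experiment reused across tests (deterministic)."""
    config = SimConfig(
        seed=11, n_true_fates=12, n_two_cys_fates=3, n_noise_peaks=40,
        n_blank_contaminants=5, n_adduct_satellites=4, n_isotope_satellites=4,
    )
    return simulate_peaklist(config)
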