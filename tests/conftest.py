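import logging

import pytest

from qmpdecomp import cohort
from qmpdecomp.calibration import qmp_profile, rmp_profile

logging.getLogger("qmpdecomp").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def default_cohort():
    """The full default cohort: 132 samples, 300+150 taxa, metabolome."""
    return cohort.simulate_cohort(seed=11)


@pytest.fixture(scope="session")
def tissue_profiles(default_cohort):
    """QMP and RMP bacterial profiles restricted to tissue samples."""
    c = default_cohort
    meta = c.metadata
    qmp, report = qmp_profile(c.counts["bacteria"], c.spikes["bacteria"], meta["mass_g"])
    rmp = rmp_profile(c.counts["bacteria"], c.spikes["bacteria"].spike_ids, seed=5)
    tissue = meta.index[meta["sample_type"] == "tissue"]
    return {
        "qmp": qmp.with_data(qmp.data[tissue.intersection(qmp.samples)]),
        "rmp": rmp.with_data(rmp.data[tissue.intersection(rmp.samples)]),
        "report": report,
        "meta": meta,
    }


@pytest.fixture(scope="session")
def trap_cohort():
    """Compositional-trap cohort: one focal taxon constant while the
    background load grows ~100x at fixed composition."""
    return cohort.simulate_cohort(
        cohort.tissue_design(seed=23),
        dynamics=cohort.trap_dynamics(seed=23),
        with_metabolites=False,
        seed=23,
    )
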