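import numpy as np
import pytest

from serpinkit import KineticScenario, ProgressCurve


@pytest.fixture
def hne_scenario() -> KineticScenario:
    """Noiseless dilution series at elastase-like assay concentrations."""
    enzyme = 2e-7
    return KineticScenario(
        ka_true=8.4e4,
        km=114e-6,
        substrate_conc=200e-6,
        enzyme_conc=enzyme,
        inhibitor_concs=[enzyme * m for m in (1, 2, 4, 6, 8, 10)],
        duration=1200.0,
        n_timepoints=61,
        noise_sd_frac=0.0,
        seed=0,
    )


@pytest.fixture
def noiseless_curve() -> ProgressCurve:
    """Exact exponential product curve, v0=1e-3 signal/s, kobs=5e-3 /s."""
    t = np.linspace(0.0, 1200.0, 61)
    v0, kobs = 1e-3, 5e-3
    return ProgressCurve(
        curve_id="clean",
        times=t,
        signal=(v0 / kobs) * (1.0 - np.exp(-kobs * t)),
        inhibitor_conc=1.0,
        enzyme_conc=0.2,
        substrate_conc=200.0,
    )


def make_curve(curve_id, times, signal, inhibitor_uM=1.0, enzyme_uM=0.2, substrate_uM=200.0):
    return ProgressCurve(
        curve_id=curve_id,
        times=np.asarray(times, float),
        signal=np.asarray(signal, float),
        inhibitor_conc=inhibitor_uM,
        enzyme_conc=enzyme_uM,
        substrate_conc=substrate_uM,
    )
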