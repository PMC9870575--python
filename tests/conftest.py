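import pytest

from ecmofick import (
    CircuitConfig,
    apply_measurement_noise,
    estimate_all_methods,
    solve_steady_state,
)

LADDER = (4000.0, 3000.0, 2000.0, 1000.0)


@pytest.fixture(scope="session")
def baseline_truths():
    """Noiseless baseline steady states over the ECMO-flow ladder."""
    return [solve_steady_state(CircuitConfig(q_ecmo=q)) for q in LADDER]


@pytest.fixture(scope="session")
def baseline_truth(baseline_truths):
    """The 2.5 L/min default operating point."""
    return solve_steady_state(CircuitConfig())


@pytest.fixture(scope="session")
def shunt_truths():
    """Noiseless 30% shunt states over the ladder."""
    return [
        solve_steady_state(CircuitConfig(q_ecmo=q, shunt_fraction=0.3))
        for q in LADDER
    ]


def estimates_for(truth, rng=None):
    """All-method estimates for one truth (noiseless unless rng given)."""
    rec = apply_measurement_noise(truth, rng=rng)
    return {
        e.method.value: e.q_lung_calc
        for e in estimate_all_methods(
            rec.window,
            rec.samples,
            q_ecmo=rec.q_ecmo,
            q_lung_ref=rec.q_lung_ref,
            fi_o2=rec.fi_o2,
            fe_o2=rec.fe_o2,
        )
    }
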