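import numpy as np
import pytest

from mockloop import (
    FlowWaveform,
    SolverSettings,
    TGA_PUMP,
    default_network,
    generate_pump_waveform,
    run_to_periodic,
)

Q_CONST = 9.133e-5  # m³/s, the TGA cycle-mean inlet flow


@pytest.fixture(scope="session")
def network():
    return default_network()


@pytest.fixture(scope="session")
def tga_waveform():
    return generate_pump_waveform(TGA_PUMP, n_samples=8000)


@pytest.fixture(scope="session")
def tga_result(network, tga_waveform):
    """Converged periodic solution of the default TGA run (shared: ~1 s)."""
    result = run_to_periodic(network, tga_waveform)
    assert result.converged
    return result


@pytest.fixture(scope="session")
def tga_tight_result(network, tga_waveform):
    """TGA run relaxed far below the default periodicity tolerance, for
    invariants that measure the quality of the periodic regime itself."""
    result = run_to_periodic(
        network, tga_waveform, SolverSettings(periodicity_tol=0.67)
    )
    assert result.converged
    return result


@pytest.fixture(scope="session")
def steady_waveform():
    n = 8000
    return FlowWaveform(
        times=np.arange(n) * 1e-4, flows=np.full(n, Q_CONST), period=0.8
    )


@pytest.fixture(scope="session")
def steady_result(network, steady_waveform):
    """Constant-inflow solution, relaxed well past the default tolerance so it
    can stand against the algebraic steady-state oracle."""
    result = run_to_periodic(
        network, steady_waveform, SolverSettings(periodicity_tol=0.67)
    )
    assert result.converged
    return result
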