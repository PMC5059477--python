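"""Shared fixtures: the default synthetic pair and channel scenarios.

Session scope keeps the expensive forced-voltage simulations to one run
each; everything here is deterministic, so sharing cannot leak state.
"""

import pytest

import bapflux as bf


@pytest.fixture(scope="session")
def params():
    return bf.default_params()


@pytest.fixture(scope="session")
def proximal_pair():
    return bf.generate_state_pair(24.0)


@pytest.fixture(scope="session")
def distal_pair():
    return bf.generate_state_pair(150.0)


@pytest.fixture(scope="session")
def equalized_pair(proximal_pair):
    return bf.splice_pair_preceding(proximal_pair, -80.0)


@pytest.fixture(scope="session")
def occluded_pair(proximal_pair):
    return bf.splice_pair_preceding(proximal_pair, -60.0)


@pytest.fixture(scope="session")
def scenarios():
    return {name: bf.build_scenario(name)
            for name in ("HI_only", "HN_only", "HN_HI")}


def state_pct(pair, scenario, window_len=1.0, window_start=0.35):
    """Percent charge change, hyperpolarized vs depolarized command."""
    qd = bf.charge_window(bf.simulate_currents(pair.depolarized, scenario),
                          window_start_after_peak_ms=window_start,
                          window_len_ms=window_len)
    qh = bf.charge_window(bf.simulate_currents(pair.hyperpolarized, scenario),
                          window_start_after_peak_ms=window_start,
                          window_len_ms=window_len)
    return bf.percent_change(qh, qd)
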