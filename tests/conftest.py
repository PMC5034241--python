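import numpy as np
import pytest

from dimerlink import (
    CaChain,
    DimerStructure,
    EntanglementTrace,
    SimConfig,
    run_unbinding,
)
from dimerlink.fixtures import CA_BOND, FixtureSpec, make_fixture


def ring_dimer(n_vertices: int) -> DimerStructure:
    """Open two-chain dimer cut from a Hopf link with protein-like bonds."""
    radius = n_vertices * CA_BOND / (2.0 * np.pi)
    fx = make_fixture(
        FixtureSpec(kind="cut_hopf_dimer", n_vertices=n_vertices, radius=radius)
    )
    a, b = fx.as_dimer_chains()
    return DimerStructure(f"CUTHOPF{n_vertices}", a, b)


@pytest.fixture(scope="session")
def cut_hopf_dimer() -> DimerStructure:
    return ring_dimer(60)


@pytest.fixture(scope="session")
def cohort_table():
    from dimerlink import load_packaged_cohort

    return load_packaged_cohort()


@pytest.fixture(scope="session")
def unbinding_trace(cut_hopf_dimer) -> tuple[DimerStructure, EntanglementTrace, SimConfig]:
    """One scaled-down dissociation ensemble shared across tests.

    90-bead synthetic dimer, 8 trajectories, 600 τ_sim: long enough for
    the entanglement (decay time ~150 τ_sim for this geometry) to relax
    to zero, short enough to keep the suite quick.
    """
    import warnings

    dimer = ring_dimer(50)
    cfg = SimConfig(n_traj=8, t_max=600.0, dt=0.01, record_every=50, seed=1234)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        trace = run_unbinding(dimer, cfg)
    return dimer, trace, cfg


def random_open_coil(n: int, seed: int, origin=(0.0, 0.0, 0.0)) -> np.ndarray:
    """Persistent random walk with 3.8 Å bonds (test helper)."""
    rng = np.random.default_rng(seed)
    pts = [np.asarray(origin, float)]
    d = rng.standard_normal(3)
    d /= np.linalg.norm(d)
    for _ in range(n - 1):
        d = d + 0.7 * rng.standard_normal(3)
        d /= np.linalg.norm(d)
        pts.append(pts[-1] + CA_BOND * d)
    return np.array(pts)
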