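import numpy as np
import pytest

import stimfret as sf


@pytest.fixture(scope="session")
def static_two_state_traces() -> list[sf.Trace]:
    """Small static two-state ensemble (0.28/70%, 0.68/30%) reused across tests."""
    return sf.simulate_state_ensemble([(0.28, 0.70), (0.68, 0.30)],
                                      n_molecules=150, seed=42)


def make_clean_trace(mol_id: str = "m0", e: float = 0.4, gamma: float = 1.0,
                     total: float = 400.0, background: float = 0.0,
                     ab: int = 150, db: int = 230, n: int = 300,
                     noise_sd: float = 0.0, seed: int = 0) -> sf.Trace:
    """Deterministic single-bleach trace built directly from the intensity model."""
    rng = np.random.default_rng(seed)
    donor = np.full(n, background + total * (1 - e) / gamma)
    acceptor = np.full(n, background + total * e)
    donor[ab:] = background + total / gamma
    acceptor[ab:] = background
    if db is not None:
        donor[db:] = background
        acceptor[db:] = background
    if noise_sd > 0:
        donor = donor + noise_sd * rng.standard_normal(n)
        acceptor = acceptor + noise_sd * rng.standard_normal(n)
    truth = sf.sim.TraceTruth(states=np.zeros(n, dtype=np.int64),
                              acceptor_bleach_frame=ab,
                              donor_bleach_frame=db, gamma=gamma,
                              state_fret=(e,))
    return sf.Trace(molecule_id=mol_id, frame_interval=0.1,
                    donor=donor, acceptor=acceptor, truth=truth)


TOY_DIMER_PDB = """\
CRYST1  100.000  100.000  100.000  90.00  90.00  90.00 P 1           1
{atoms}
END
"""


def toy_dimer_pdb(path, n_res: int = 10, spacing: float = 20.0) -> None:
    """Two-chain poly-ALA toy model: chain A along x, chain B offset in z.

    Residues are spaced widely so every site is sterically open.
    """
    lines = []
    serial = 1
    for chain, z in (("A", 0.0), ("B", spacing * 2)):
        for i in range(1, n_res + 1):
            x = i * spacing
            for name, dx in (("N", -0.8), ("CA", 0.0), ("C", 0.8), ("CB", 0.3)):
                elem = name[0]
                name4 = f" {name:<3s}"
                lines.append(
                    f"ATOM  {serial:5d} {name4} ALA {chain}{i:4d}    "
                    f"{x + dx:8.3f}{0.0:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}"
                    f"          {elem:>2s}")
                serial += 1
    path.write_text(TOY_DIMER_PDB.format(atoms="\n".join(lines)))


@pytest.fixture()
def toy_pdb(tmp_path):
    p = tmp_path / "toy_dimer.pdb"
    toy_dimer_pdb(p)
    return p
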