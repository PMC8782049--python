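import pytest

from heteropka import (CompoundRecord, Microstate, Phase, Step,
                       fixture_tables, simulate_dataset)


@pytest.fixture(scope="session")
def tables():
    return fixture_tables()


@pytest.fixture()
def uracil_like_record():
    """A compound with the tautomer multiplicity typical of uracil:
    3 cationic, 6 neutral, 2 anionic aqueous microstates.  Energies are
    synthetic; the representative of each charge state is the minimum."""
    def ms(charge, tid, energy):
        return Microstate("uracil-like", charge, tid, Phase.AQUEOUS, energy)

    microstates = (
        [ms(1, f"c{i}", e) for i, e in enumerate([-5000.0, -4968.0, -4940.0])]
        + [ms(0, f"n{i}", e) for i, e in
           enumerate([-6200.0, -6168.0, -6150.0, -6120.0, -6090.0, -6060.0])]
        + [ms(-1, f"a{i}", e) for i, e in enumerate([-7400.0, -7360.0])])
    return CompoundRecord("uracil-like", microstates=microstates)


@pytest.fixture(scope="session")
def noiseless_sim():
    return simulate_dataset(n_compounds=12, noise_sd=0.0, replicate_sd=0.0,
                            seed=97, step=Step.PKA1)
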