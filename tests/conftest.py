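import numpy as np
import pytest

from lidmsm.synthetic import (
    SyntheticChainSpec,
    default_chain_spec,
    planted_four_state_matrix,
    sample_lengths,
    simulate_chain,
)


def make_atom_array(coords, res_ids, atom_names=None, elements=None):
    """Small helper: build a biotite AtomArray from plain arrays."""
    import biotite.structure as struc

    coords = np.asarray(coords, dtype=float)
    n = coords.shape[0]
    atoms = struc.AtomArray(n)
    atoms.coord = coords
    atoms.res_id = np.asarray(res_ids, dtype=int)
    atoms.atom_name = np.asarray(atom_names if atom_names is not None else ["CA"] * n)
    atoms.element = np.asarray(elements if elements is not None else ["C"] * n)
    atoms.res_name = np.asarray(["ALA"] * n)
    atoms.chain_id = np.asarray(["A"] * n)
    return atoms


@pytest.fixture(scope="session")
def two_state_spec():
    T = np.array([[0.9, 0.1], [0.2, 0.8]])
    means = np.array([[0.0, 0.0], [3.0, 3.0]])
    return SyntheticChainSpec(
        n_states=2,
        T_true=T,
        emission_means=means,
        emission_sd=0.3,
        n_features=2,
        length_mean=500,
        length_max=1000,
        n_trajectories=20,
        n_initial_states=2,
        seed=11,
    )


@pytest.fixture(scope="session")
def planted_chain_data():
    """Medium-size ensemble from the planted 4-state chain (shared, read-only)."""
    spec = default_chain_spec(seed=3, n_trajectories=60, length_mean=400,
                              length_max=2000)
    lengths = sample_lengths(spec)
    labels, features = simulate_chain(spec, lengths)
    return spec, labels, features


@pytest.fixture(scope="session")
def planted_T():
    return planted_four_state_matrix()
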