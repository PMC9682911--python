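import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

from azogp import data, gp  # noqa: E402


@pytest.fixture(scope="session")
def synth_small():
    """Fully-labelled synthetic multitask dataset, 60 molecules."""
    spec = data.SyntheticDatasetSpec(
        n_molecules=60, feature_length=48, label_missingness=(0, 0, 0, 0),
        seed=7,
    )
    X, Y, gt = data.generate_synthetic_dataset(spec)
    return X, Y, gt


@pytest.fixture(scope="session")
def azo_smiles():
    """A handful of valid azoarene SMILES spanning simple substitutions."""
    return [
        "c1ccc(/N=N/c2ccccc2)cc1",                    # azobenzene
        "Cc1ccc(/N=N/c2ccccc2)cc1",                   # 4-methyl
        "COc1ccc(/N=N/c2ccccc2)cc1",                  # 4-methoxy
        "Nc1ccc(/N=N/c2ccccc2)cc1",                   # 4-amino
        "O=[N+]([O-])c1ccc(/N=N/c2ccccc2)cc1",        # 4-nitro
        "Fc1ccc(/N=N/c2ccccc2)cc1",                   # 4-fluoro
        "Clc1ccc(/N=N/c2ccccc2)cc1",                  # 4-chloro
        "Brc1ccc(/N=N/c2ccccc2)cc1",                  # 4-bromo
        "CN(C)c1ccc(/N=N/c2ccccc2)cc1",               # 4-dimethylamino
        "Oc1ccc(/N=N/c2ccccc2)cc1",                   # 4-hydroxy
        "CC(=O)c1ccc(/N=N/c2ccccc2)cc1",              # 4-acetyl
        "N#Cc1ccc(/N=N/c2ccccc2)cc1",                 # 4-cyano
        "c1ccc(/N=N/c2ccncc2)cc1",                    # azopyridine
        "Cc1cc(C)n(-c2ccccc2)n1",                     # pyrazole (no azo)
    ]


def make_mogp_state(features, observations, L, sigma_f2=1.0, sigma_y2=0.1,
                    task_means=None, task_stds=None, n_tasks=4):
    """Assemble an MOGPState with prescribed hyperparameters.

    The Cholesky/alpha are recomputed with the package's own numerics; the
    prescribed parameters bypass fitting so posterior algebra can be
    checked against independent oracles.
    """
    from scipy.linalg import cholesky, solve_triangular

    features = np.atleast_2d(np.asarray(features, dtype=float))
    mol_idx, task_idx, values = gp._normalise_observations(observations)
    L = np.asarray(L, dtype=float)
    B = L @ L.T
    if task_means is None:
        task_means = np.zeros(n_tasks)
    if task_stds is None:
        task_stds = np.ones(n_tasks)
    z = (values - task_means[task_idx]) / task_stds[task_idx]
    T_obs = gp.tanimoto_matrix(features)[np.ix_(mol_idx, mol_idx)]
    K = sigma_f2 * T_obs * B[np.ix_(task_idx, task_idx)] \
        + sigma_y2 * np.eye(len(z))
    Lc = cholesky(K + 1e-12 * np.eye(len(z)), lower=True)
    alpha = solve_triangular(Lc.T, solve_triangular(Lc, z, lower=True),
                             lower=False)
    return gp.MOGPState(
        X_mols=features, mol_idx=mol_idx, task_idx=task_idx, z=z,
        task_means=np.asarray(task_means, dtype=float),
        task_stds=np.asarray(task_stds, dtype=float),
        coreg=gp.Coregionalisation(L=L), sigma_f2=sigma_f2,
        sigma_y2=np.array([sigma_y2]), chol=Lc, alpha=alpha,
        jitter=1e-12, n_tasks=n_tasks,
    )
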