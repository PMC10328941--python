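"""PCoA and symmetric Procrustes with a permutation test (PROTEST)."""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from skbio import DistanceMatrix

__all__ = ["Ordination", "ProcrustesResult", "pcoa", "procrustes", "protest"]


@dataclass
class Ordination:
    sample_ids: list[str]
    coordinates: np.ndarray           # samples x retained axes
    eigenvalues: np.ndarray           # descending, > 0
    proportion_explained: np.ndarray
    negative_eigenvalue_mass: float = 0.0

    def coords_df(self) -> pd.DataFrame:
        cols = [f"axis{i + 1}" for i in range(self.coordinates.shape[1])]
        return pd.DataFrame(self.coordinates, index=self.sample_ids,
                            columns=cols)


@dataclass
class ProcrustesResult:
    m2: float
    r: float
    p_value: float | None = None
    n_permutations: int = 0
    seed: int | None = None
    k_axes: int = 0


def pcoa(dm: DistanceMatrix, n_axes: int | None = None) -> Ordination:
    """Classical metric scaling: Gower double-centering of -D^2/2, then
    eigendecomposition. Coordinates are eigenvectors scaled by the square
    root of their (positive) eigenvalues; negative eigenvalues are
    dropped and their total magnitude recorded.
    """
    ids = list(dm.ids)
    n = len(ids)
    if n < 3:
        raise ValueError("PCoA needs >= 3 samples")
    D2 = dm.data ** 2
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ D2 @ J
    vals, vecs = np.linalg.eigh((B + B.T) / 2)
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]
    tol = max(1e-12, 1e-10 * abs(vals).max()) if vals.size else 0.0
    pos = vals > tol
    if not pos.any():
        raise ValueError("no positive eigenvalue: matrix carries no "
                         "Euclidean structure")
    neg_mass = float(np.abs(vals[vals < -tol]).sum())
    vals_p = vals[pos]
    coords = vecs[:, pos] * np.sqrt(vals_p)
    if n_axes is not None:
        coords = coords[:, :n_axes]
        vals_p = vals_p[:n_axes]
    return Ordination(
        sample_ids=ids,
        coordinates=coords,
        eigenvalues=vals_p,
        proportion_explained=vals_p / vals[pos].sum(),
        negative_eigenvalue_mass=neg_mass,
    )


def _aligned_configs(ord1: Ordination, ord2: Ordination,
                     k_axes: int | None) -> tuple[np.ndarray, np.ndarray, int]:
    shared = [s for s in ord1.sample_ids if s in set(ord2.sample_ids)]
    if len(shared) < 3:
        raise ValueError("fewer than 3 shared sample ids")
    i1 = [ord1.sample_ids.index(s) for s in shared]
    i2 = [ord2.sample_ids.index(s) for s in shared]
    k = min(ord1.coordinates.shape[1], ord2.coordinates.shape[1])
    if k_axes is not None:
        k = min(k, k_axes)
    X = ord1.coordinates[i1, :k].astype(float)
    Y = ord2.coordinates[i2, :k].astype(float)
    return X, Y, k


def _normalize(M: np.ndarray) -> np.ndarray:
    M = M - M.mean(axis=0)
    ss = np.sqrt((M ** 2).sum())
    if ss == 0:
        raise ValueError("degenerate configuration: all points identical")
    return M / ss


def _m2(X: np.ndarray, Y: np.ndarray) -> float:
    """Symmetric Procrustes residual: both configurations centered and
    scaled to unit sum-of-squares; optimal rotation (reflections allowed)
    gives m2 = 1 - (sum of singular values of X'Y)^2."""
    sv = np.linalg.svd(X.T @ Y, compute_uv=False)
    return float(max(0.0, 1.0 - sv.sum() ** 2))


def procrustes(ord1: Ordination, ord2: Ordination,
               k_axes: int | None = None) -> ProcrustesResult:
    """Symmetric Procrustes superimposition of two ordinations aligned by
    sample id; r = sqrt(1 - m2)."""
    X, Y, k = _aligned_configs(ord1, ord2, k_axes)
    m2 = _m2(_normalize(X), _normalize(Y))
    return ProcrustesResult(m2=m2, r=float(np.sqrt(1.0 - m2)), k_axes=k)


def protest(ord1: Ordination, ord2: Ordination,
            n_permutations: int = 100_000, seed: int = 0,
            k_axes: int | None = None) -> ProcrustesResult:
    """Permutation test of the Procrustes correlation: the rows of the
    second configuration are shuffled; p = (1 + #{r_perm >= r_obs}) /
    (1 + n_permutations)."""
    if n_permutations < 1:
        raise ValueError("n_permutations must be >= 1")
    X, Y, k = _aligned_configs(ord1, ord2, k_axes)
    Xn, Yn = _normalize(X), _normalize(Y)
    m2_obs = _m2(Xn, Yn)
    r_obs = float(np.sqrt(1.0 - m2_obs))
    rng = np.random.default_rng(seed)
    hits = 0
    n = Xn.shape[0]
    for _ in range(n_permutations):
        perm = rng.permutation(n)
        r_i = float(np.sqrt(1.0 - _m2(Xn, Yn[perm])))
        if r_i >= r_obs - 1e-12:
            hits += 1
    p = (1 + hits) / (1 + n_permutations)
    return ProcrustesResult(m2=m2_obs, r=r_obs, p_value=p,
                            n_permutations=n_permutations, seed=seed,
                            k_axes=k)


def write_ordination_tsv(ordn: Ordination, path) -> None:
    df = ordn.coords_df()
    df.index.name = "sample"
    df.to_csv(path, sep="\t")
    with open(str(path) + ".eig.json", "w") as fh:
        json.dump({
            "eigenvalues": ordn.eigenvalues.tolist(),
            "proportion_explained": ordn.proportion_explained.tolist(),
            "negative_eigenvalue_mass": ordn.negative_eigenvalue_mass,
        }, fh, indent=1)


def read_ordination_tsv(path) -> Ordination:
    df = pd.read_csv(path, sep="\t", index_col=0)
    coords = df.to_numpy(dtype=float)
    eig = None
    try:
        with open(str(path) + ".eig.json") as fh:
            eig = json.load(fh)
    except FileNotFoundError:
        pass
    if eig:
        vals = np.asarray(eig["eigenvalues"])
        prop = np.asarray(eig["proportion_explained"])
        neg = float(eig.get("negative_eigenvalue_mass", 0.0))
    else:
        vals = (coords ** 2).sum(axis=0)
        prop = vals / vals.sum()
        neg = 0.0
    return Ordination(list(df.index), coords, vals, prop, neg)
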