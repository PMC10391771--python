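"""Pedigree, genomic and combined relationship matrices.

* ``build_A`` — numerator relationship matrix by the tabular method, with
  inbreeding; ``build_A_inverse`` — sparse inverse by Henderson's rules
  (mendelian-sampling variances adjusted for parental inbreeding).
* ``build_G`` — VanRaden method-1 genomic matrix ``ZZ' / (2 Σ p_j(1-p_j))``
  with observed (or supplied) allele frequencies; monomorphic SNPs dropped.
* ``build_H_inverse`` — single-step matrix combining both:
  ``H⁻¹ = A⁻¹ + [0 0; 0 G*⁻¹ − A₂₂⁻¹]`` where ``G*`` is G rescaled so its
  mean diagonal/off-diagonal match A₂₂ and blended ``0.95 G + 0.05 A₂₂``
  to guarantee invertibility.
* ``gene_drop_A`` — Monte-Carlo identity-by-descent estimate of A by gene
  dropping, an independent check of the tabular method.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import sparse

__all__ = [
    "sort_pedigree",
    "build_A",
    "build_A_inverse",
    "build_G",
    "build_H_inverse",
    "gene_drop_A",
]


def sort_pedigree(ped: pd.DataFrame) -> pd.DataFrame:
    """Topologically sort id/sire/dam rows so parents precede offspring.

    Unknown parents are coded 0. Raises on cycles or on parents that never
    appear as animals.
    """
    ids = ped["id"].to_numpy()
    known = set(ids)
    for col in ("sire", "dam"):
        parents = set(ped[col]) - {0}
        if not parents <= known:
            raise ValueError(f"unknown animals referenced as {col}: {sorted(parents - known)[:5]}")
    order: list = []
    placed: set = set()
    remaining = ped[["id", "sire", "dam"]].to_numpy().tolist()
    while remaining:
        progress = False
        next_round = []
        for row in remaining:
            i, s, d = row
            if (s == 0 or s in placed) and (d == 0 or d in placed):
                order.append(i)
                placed.add(i)
                progress = True
            else:
                next_round.append(row)
        if not progress:
            raise ValueError("pedigree contains a cycle")
        remaining = next_round
    return ped.set_index("id").loc[order].reset_index()


def build_A(ped: pd.DataFrame, assume_sorted: bool = False) -> tuple[np.ndarray, list]:
    """Numerator relationship matrix (tabular method). Returns (A, id order)."""
    if not assume_sorted:
        ped = sort_pedigree(ped)
    ids = ped["id"].tolist()
    idx = {a: i for i, a in enumerate(ids)}
    n = len(ids)
    A = np.zeros((n, n))
    sires = [idx.get(s, -1) for s in ped["sire"]]
    dams = [idx.get(d, -1) for d in ped["dam"]]
    for i in range(n):
        s, d = sires[i], dams[i]
        row = np.zeros(i)
        if s >= 0:
            row += 0.5 * A[s, :i]
        if d >= 0:
            row += 0.5 * A[d, :i]
        A[i, :i] = row
        A[:i, i] = row
        A[i, i] = 1.0 + (0.5 * A[s, d] if s >= 0 and d >= 0 else 0.0)
    return A, ids


def build_A_inverse(
    ped: pd.DataFrame, inbreeding: np.ndarray | None = None, assume_sorted: bool = False
) -> tuple[sparse.csr_matrix, list]:
    """Sparse A-inverse by Henderson's rules with inbreeding.

    ``inbreeding`` may be supplied (aligned with the sorted pedigree); by
    default it is taken from the tabular A diagonal.
    """
    if not assume_sorted:
        ped = sort_pedigree(ped)
    ids = ped["id"].tolist()
    idx = {a: i for i, a in enumerate(ids)}
    n = len(ids)
    if inbreeding is None:
        A, _ = build_A(ped, assume_sorted=True)
        inbreeding = np.diag(A) - 1.0
    F = np.asarray(inbreeding, dtype=float)
    rows, cols, vals = [], [], []

    def add(i, j, v):
        rows.append(i)
        cols.append(j)
        vals.append(v)

    for i, (s_id, d_id) in enumerate(zip(ped["sire"], ped["dam"])):
        s = idx.get(s_id, -1)
        d = idx.get(d_id, -1)
        if s >= 0 and d >= 0:
            m = 0.5 - 0.25 * (F[s] + F[d])
        elif s >= 0 or d >= 0:
            p = s if s >= 0 else d
            m = 0.75 - 0.25 * F[p]
        else:
            m = 1.0
        alpha = 1.0 / m
        add(i, i, alpha)
        for p in (s, d):
            if p >= 0:
                add(i, p, -alpha / 2.0)
                add(p, i, -alpha / 2.0)
        for p in (s, d):
            for q in (s, d):
                if p >= 0 and q >= 0:
                    add(p, q, alpha / 4.0)
    Ainv = sparse.csr_matrix((vals, (rows, cols)), shape=(n, n))
    return Ainv, ids


def build_G(dosages: pd.DataFrame | np.ndarray, freqs: np.ndarray | None = None) -> np.ndarray:
    """VanRaden method-1 genomic relationship matrix from 0/1/2 dosages."""
    if isinstance(dosages, pd.DataFrame):
        M = dosages.to_numpy(dtype=float)
    else:
        M = np.asarray(dosages, dtype=float)
    p = M.mean(axis=0) / 2.0 if freqs is None else np.asarray(freqs, dtype=float)
    poly = (p > 0) & (p < 1)
    if not poly.any():
        raise ValueError("all SNPs are monomorphic")
    M, p = M[:, poly], p[poly]
    Z = M - 2.0 * p
    denom = 2.0 * np.sum(p * (1.0 - p))
    return Z @ Z.T / denom


def build_H_inverse(
    A: np.ndarray,
    A_inv,
    G: np.ndarray,
    genotyped_idx: np.ndarray,
    blend: float = 0.05,
) -> np.ndarray:
    """Single-step H-inverse from pedigree and genomic information.

    ``genotyped_idx`` indexes the genotyped animals within the pedigree
    ordering of ``A``/``A_inv`` (rows of ``G`` in the same order). G is first
    rescaled so its mean diagonal and mean off-diagonal equal those of A22,
    then blended ``(1-blend)*G + blend*A22``.
    """
    g = np.asarray(genotyped_idx)
    A22 = A[np.ix_(g, g)]
    n2 = len(g)
    if n2 == 0:
        return np.asarray(A_inv.todense()) if sparse.issparse(A_inv) else np.array(A_inv, dtype=float)
    off = ~np.eye(n2, dtype=bool)
    if n2 > 1 and not np.isclose(np.mean(np.diag(G)), np.mean(G[off])):
        b = (np.mean(np.diag(A22)) - np.mean(A22[off])) / (np.mean(np.diag(G)) - np.mean(G[off]))
        a = np.mean(A22[off]) - b * np.mean(G[off])
    else:
        a, b = 0.0, 1.0
    G_star = (1.0 - blend) * (a + b * G) + blend * A22
    try:
        np.linalg.cholesky(G_star)
    except np.linalg.LinAlgError as err:
        raise np.linalg.LinAlgError(
            "blended G* is singular; raise the blend weight towards A22"
        ) from err
    Hinv = np.asarray(A_inv.todense(), dtype=float) if sparse.issparse(A_inv) else np.array(A_inv, dtype=float)
    correction = np.linalg.inv(G_star) - np.linalg.inv(A22)
    Hinv[np.ix_(g, g)] += correction
    return Hinv


def gene_drop_A(ped: pd.DataFrame, n_reps: int = 100_000, seed: int = 0) -> tuple[np.ndarray, list]:
    """Monte-Carlo estimate of A from identity-by-descent gene dropping.

    Each founder gets two unique alleles; alleles drop through the pedigree
    with independent 50/50 picks per replicate. ``A[i,j]`` is estimated as
    twice the mean coancestry (probability a random allele from i is IBD to
    a random allele from j); the diagonal as 1 + P(the two alleles of i are
    IBD). Standard errors shrink as 1/sqrt(n_reps).
    """
    ped = sort_pedigree(ped)
    ids = ped["id"].tolist()
    idx = {a: i for i, a in enumerate(ids)}
    n = len(ids)
    rng = np.random.default_rng(seed)
    alleles = np.zeros((n_reps, n, 2), dtype=np.int16)
    next_allele = 0
    for i, (s_id, d_id) in enumerate(zip(ped["sire"], ped["dam"])):
        for slot, p_id in enumerate((s_id, d_id)):
            if p_id == 0:
                alleles[:, i, slot] = next_allele
                next_allele += 1
            else:
                p = idx[p_id]
                pick = rng.integers(0, 2, n_reps)
                alleles[:, i, slot] = alleles[np.arange(n_reps), p, pick]
    A = np.zeros((n, n))
    for i in range(n):
        for j in range(i, n):
            if i == j:
                A[i, i] = 1.0 + np.mean(alleles[:, i, 0] == alleles[:, i, 1])
            else:
                f = sum(
                    np.mean(alleles[:, i, a] == alleles[:, j, b])
                    for a in (0, 1) for b in (0, 1)
                ) / 4.0
                A[i, j] = A[j, i] = 2.0 * f
    return A, ids
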