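"""Divergence estimation between aligned SRCR domains.

The working estimate is the uncorrected p-distance (proportion of
differing sites) computed with pairwise deletion: a column contributes to
a pair only if neither row holds a gap or ``X``.  Standard errors come
from column bootstrap; the closed form ``sqrt(p(1-p)/L)`` is the analytic
check the bootstrap converges to.  Distance corrections for tree building
are the Poisson transform and a one-parameter empirical-matrix (JTT)
model fitted by matrix exponentiation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.linalg import expm
from scipy.optimize import brentq

from .msa import DomainAlignment

#: characters excluded from the p-distance denominator
_SKIP = frozenset("-X.")

_JTT_ORDER = "ARNDCQEGHILKMFPSTWYV"


class DistanceError(ValueError):
    pass


@dataclass
class DistanceMatrix:
    """Symmetric divergence matrix with optional bootstrap SEs.

    ``values[i, j]`` is the divergence between ``labels[i]`` and
    ``labels[j]`` (NaN where undefined); ``se`` parallels ``values``;
    ``L_effective[i, j]`` is the per-pair compared-column count.
    """

    labels: list[str]
    values: np.ndarray
    se: np.ndarray | None = None
    L_effective: np.ndarray | None = None
    model_tag: str = "p"

    def __post_init__(self) -> None:
        n = len(self.labels)
        if self.values.shape != (n, n):
            raise DistanceError("matrix shape does not match labels")
        if not np.allclose(np.nan_to_num(self.values),
                           np.nan_to_num(self.values.T)):
            raise DistanceError("matrix not symmetric")

    def get(self, a: str, b: str) -> float:
        i, j = self.labels.index(a), self.labels.index(b)
        return float(self.values[i, j])

    def submatrix(self, row_labels, col_labels) -> pd.DataFrame:
        """Rectangular extraction (rows = one protein's domains, columns =
        another's), the layout of printed divergence tables."""
        ri = [self.labels.index(l) for l in row_labels]
        ci = [self.labels.index(l) for l in col_labels]
        return pd.DataFrame(self.values[np.ix_(ri, ci)],
                            index=row_labels, columns=col_labels)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.labels,
                            columns=self.labels)


def p_distance(row_a: str, row_b: str, deletion_mode: str = "pairwise",
               mask: np.ndarray | None = None):
    """p-distance of two equal-length aligned rows.

    Returns ``(p, L_effective)``; ``p`` is ``None`` when no column is
    comparable (never reported as 0).  ``deletion_mode="complete"``
    requires a precomputed ``mask`` of globally kept columns.
    """
    if len(row_a) != len(row_b):
        raise DistanceError("rows differ in length")
    if deletion_mode not in ("pairwise", "complete"):
        raise DistanceError(f"unknown deletion mode {deletion_mode!r}")
    diff = n = 0
    for k, (x, y) in enumerate(zip(row_a, row_b)):
        if mask is not None and not mask[k]:
            continue
        if x in _SKIP or y in _SKIP:
            continue
        n += 1
        diff += x != y
    if n == 0:
        return None, 0
    return diff / n, n


def analytic_se(p: float, L: int) -> float:
    """Closed-form standard error of a p-distance over ``L`` sites:
    ``sqrt(p(1-p)/L)``."""
    if not 0 <= p <= 1:
        raise DistanceError("p outside [0, 1]")
    if L < 1:
        raise DistanceError("L must be >= 1")
    return math.sqrt(p * (1 - p) / L)


def bootstrap_se(row_a: str, row_b: str, B: int = 1000,
                 seed: int | None = None,
                 deletion_mode: str = "pairwise") -> float:
    """Column-bootstrap standard error of the p-distance.

    Resamples the alignment columns with replacement ``B`` times and
    returns the standard deviation of the resampled distances.
    """
    if B < 100:
        raise DistanceError("B must be >= 100")
    if seed is None:
        raise DistanceError("bootstrap requires an explicit seed")
    p0, L = p_distance(row_a, row_b, deletion_mode)
    if p0 is None:
        raise DistanceError("no comparable columns")
    ncol = len(row_a)
    comparable = np.array([x not in _SKIP and y not in _SKIP
                           for x, y in zip(row_a, row_b)])
    differs = np.array([x != y for x, y in zip(row_a, row_b)])
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, ncol, size=(B, ncol))
    comp = comparable[idx]
    dif = differs[idx] & comp
    ns = comp.sum(axis=1)
    with np.errstate(invalid="ignore"):
        ps = np.where(ns > 0, dif.sum(axis=1) / np.maximum(ns, 1), np.nan)
    return float(np.nanstd(ps, ddof=0))


# ---------------------------------------------------------------------------
# Distance corrections

def _load_jtt():
    """Shipped JTT replacement model -> (rate matrix Q, frequencies pi),
    Q scaled to one expected substitution per unit time."""
    path = resources.files("srcrpipe").joinpath("data/jtt_rates.tsv")
    lines = [l for l in path.read_text().splitlines()
             if l.strip() and not l.startswith("#")]
    S = np.zeros((20, 20))
    for i, line in enumerate(lines[:19], start=1):
        for j, v in enumerate(line.split("\t")):
            S[i, j] = S[j, i] = float(v)
    pi = np.array([float(x) for x in lines[19].split("\t")])
    Q = S * pi[None, :]
    np.fill_diagonal(Q, 0.0)
    np.fill_diagonal(Q, -Q.sum(axis=1))
    mu = -(pi * np.diag(Q)).sum()
    return Q / mu, pi


_JTT: tuple[np.ndarray, np.ndarray] | None = None


def _jtt_expected_p(t: float) -> float:
    """Expected proportion of differing sites after time ``t`` under the
    JTT model at equilibrium."""
    global _JTT
    if _JTT is None:
        _JTT = _load_jtt()
    Q, pi = _JTT
    P = expm(Q * t)
    return float(1.0 - (pi * np.diag(P)).sum())


def jtt_saturation() -> float:
    """Limiting expected p as t -> inf: ``1 - sum(pi_i^2)``."""
    global _JTT
    if _JTT is None:
        _JTT = _load_jtt()
    _, pi = _JTT
    return float(1.0 - (pi ** 2).sum())


def correct_distance(p: float, model_tag: str = "p") -> float:
    """Transform a p-distance into substitutions/site under a model.

    ``p`` returns the input; ``poisson`` gives ``-ln(1-p)``; ``jtt_like``
    inverts the expected-difference curve of the JTT rate matrix (the
    maximum-likelihood distance when the data are summarized as
    differ/agree counts).  Saturated inputs return ``inf``.
    """
    if model_tag == "p":
        return p
    if model_tag == "poisson":
        if p >= 1.0:
            return math.inf
        if p < 0:
            raise DistanceError("negative p")
        return -math.log1p(-p)
    if model_tag == "jtt_like":
        if p < 0:
            raise DistanceError("negative p")
        if p >= jtt_saturation():
            return math.inf
        if p == 0:
            return 0.0
        return float(brentq(lambda t: _jtt_expected_p(t) - p,
                            1e-9, 50.0, xtol=1e-10))
    raise DistanceError(f"unknown model {model_tag!r}")


# ---------------------------------------------------------------------------
# Matrices

def distance_matrix(alignment: DomainAlignment, model_tag: str = "p",
                    deletion_mode: str = "pairwise", B: int = 0,
                    seed: int | None = None) -> DistanceMatrix:
    """All-pairs divergence matrix over an alignment's rows; bootstrap SEs
    filled when ``B > 0`` (seed then mandatory)."""
    rows = alignment.rows
    if len(rows) < 2:
        raise DistanceError("need at least 2 rows")
    n = len(rows)
    mask = None
    if deletion_mode == "complete":
        ncol = alignment.column_count
        mask = np.ones(ncol, dtype=bool)
        for _, s in rows:
            for k, ch in enumerate(s):
                if ch in _SKIP:
                    mask[k] = False
    vals = np.zeros((n, n))
    Ls = np.zeros((n, n), dtype=int)
    ses = np.zeros((n, n)) if B > 0 else None
    for i in range(n):
        for j in range(i + 1, n):
            p, L = p_distance(rows[i][1], rows[j][1], deletion_mode, mask)
            if p is None:
                vals[i, j] = vals[j, i] = np.nan
                continue
            d = correct_distance(p, model_tag)
            vals[i, j] = vals[j, i] = d
            Ls[i, j] = Ls[j, i] = L
            if B > 0:
                se = bootstrap_se(rows[i][1], rows[j][1], B,
                                  seed=_pair_seed(seed, i, j),
                                  deletion_mode=deletion_mode)
                ses[i, j] = ses[j, i] = se
    labels = [l for l, _ in rows]
    return DistanceMatrix(labels=labels, values=vals, se=ses,
                          L_effective=Ls, model_tag=model_tag)


def _pair_seed(seed: int | None, i: int, j: int) -> int:
    if seed is None:
        raise DistanceError("bootstrap requires an explicit seed")
    return (seed * 1_000_003 + i * 1031 + j) % (2 ** 31)


# ---------------------------------------------------------------------------
# Table rendering / TSV

def write_distance_tsv(matrix: DistanceMatrix, path: str | Path,
                       se_path: str | Path | None = None) -> None:
    matrix.to_frame().to_csv(path, sep="\t", float_format="%.6f")
    if se_path is not None and matrix.se is not None:
        pd.DataFrame(matrix.se, index=matrix.labels,
                     columns=matrix.labels).to_csv(
            se_path, sep="\t", float_format="%.6f")


def read_distance_tsv(path: str | Path) -> DistanceMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return DistanceMatrix(labels=[str(c) for c in df.columns],
                          values=df.to_numpy(dtype=float))


def render_paper_table(matrix: DistanceMatrix, row_labels, col_labels) -> str:
    """Render a rectangular block in the printed-table style: each cell
    ``0.ddd`` over ``(0.ddd)`` when SEs are present."""
    ri = [matrix.labels.index(l) for l in row_labels]
    ci = [matrix.labels.index(l) for l in col_labels]
    width = max(len(l) for l in list(row_labels) + [""]) + 2
    out = [" " * width + "\t".join(f"{l:>8}" for l in col_labels)]
    for i, rl in zip(ri, row_labels):
        vals = "\t".join(f"{matrix.values[i, j]:8.3f}" for j in ci)
        out.append(f"{rl:<{width}}" + vals)
        if matrix.se is not None:
            ses = "\t".join(f"({matrix.se[i, j]:.3f})".rjust(8) for j in ci)
            out.append(" " * width + ses)
    return "\n".join(out)
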