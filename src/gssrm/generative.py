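"""Generative side of the group-structured social relations model.

The latent propensity of actor i (household k) to support partner j
(household l) is

    y*_ik,jl = x_ik,jl beta + a2_k + a1_ik + b2_l + b1_jl
               + c_ik,l + d_k,jl + h_k,l + u_|ik,jl| + e_ik,jl,

with e ~ N(0, 1) and the observed nomination y = 1{y* >= 0}.  Eight
random-effect blocks partition the unexplained variance: household
giving/receiving (a2, b2), individual giving/receiving (a1, b1),
actor-to-group and group-to-actor effects (c, d), directed
household-pair effects (h) and the symmetric individual-dyad effect
(u).  Four free correlations tie the blocks into reciprocities: the
(a2, b2) and (a1, b1) pairs (generalized reciprocity at the two
levels), the (c_ik,l, d_l,ik) pairing (an individual's giving to a
household with that household's giving back to the individual), and
corr(h_kl, h_lk) (group-level dyadic reciprocity).  The symmetric u
induces the individual-level dyadic reciprocity sigma_u^2 /
(sigma_u^2 + 1).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .covariates import DesignMatrix

__all__ = [
    "GSSRMParameters",
    "NetworkStructure",
    "RandomEffectRealization",
    "NetworkDataset",
    "draw_random_effects",
    "latent_response",
    "simulate_network",
    "transpose_dataset",
]

VARIANCE_NAMES = [
    "var_a2",
    "var_b2",
    "var_a1",
    "var_b1",
    "var_c",
    "var_d",
    "var_h",
    "var_u",
]
CORRELATION_NAMES = ["rho_a2b2", "rho_a1b1", "rho_cd", "rho_hh"]


@dataclass
class GSSRMParameters:
    """Fixed effects, eight variance components and four correlations.

    ``beta`` maps design-column names to coefficients (missing columns
    default to 0 when evaluated against a design).  The probit residual
    variance is fixed at 1 for identification and is not a field.
    """

    beta: dict[str, float] = field(default_factory=dict)
    var_a2: float = 0.0
    var_b2: float = 0.0
    var_a1: float = 0.0
    var_b1: float = 0.0
    var_c: float = 0.0
    var_d: float = 0.0
    var_h: float = 0.0
    var_u: float = 0.0
    rho_a2b2: float = 0.0
    rho_a1b1: float = 0.0
    rho_cd: float = 0.0
    rho_hh: float = 0.0

    def __post_init__(self) -> None:
        for name in VARIANCE_NAMES:
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        for name in CORRELATION_NAMES:
            rho = getattr(self, name)
            if not -1.0 <= rho <= 1.0:
                raise ValueError(f"{name} must lie in [-1, 1]")

    @property
    def variances(self) -> dict[str, float]:
        return {name: float(getattr(self, name)) for name in VARIANCE_NAMES}

    def beta_vector(self, columns: list[str]) -> np.ndarray:
        unknown = set(self.beta) - set(columns)
        if unknown:
            raise KeyError(f"beta names not in design: {sorted(unknown)}")
        return np.array([self.beta.get(c, 0.0) for c in columns], dtype=float)


def _bivariate_cov(v1: float, v2: float, rho: float, label: str) -> np.ndarray:
    cov = rho * np.sqrt(v1 * v2)
    mat = np.array([[v1, cov], [cov, v2]])
    if np.linalg.eigvalsh(mat).min() < -1e-12:
        raise ValueError(f"{label} covariance block is not positive semi-definite")
    return mat


class NetworkStructure:
    """Index maps from directed dyad rows to random-effect levels.

    Rows are directed inter-household observations (actor i of
    household k -> partner j of household l).  For each row the
    structure stores integer codes into: households (ka, kb),
    individuals (ia, ib), (individual, foreign-household) pairs used by
    both c and d (cg for the actor side, dg for the partner side),
    unordered household pairs with an orientation slot (hq, hslot), and
    unordered individual dyads (ud).
    """

    def __init__(self, frame: pd.DataFrame):
        for col in ("actor", "actor_household", "partner", "partner_household"):
            if col not in frame.columns:
                raise ValueError(f"dyad table lacks column {col!r}")
        if (frame["actor_household"] == frame["partner_household"]).any():
            raise ValueError("dyad table contains intra-household rows")
        actor = frame["actor"].astype(str).to_numpy()
        partner = frame["partner"].astype(str).to_numpy()
        ahh = frame["actor_household"].astype(str).to_numpy()
        phh = frame["partner_household"].astype(str).to_numpy()

        self.households = sorted(set(ahh) | set(phh))
        self.individuals = sorted(set(actor) | set(partner))
        hh_code = {h: c for c, h in enumerate(self.households)}
        ind_code = {i: c for c, i in enumerate(self.individuals)}
        self.ka = np.array([hh_code[h] for h in ahh])
        self.kb = np.array([hh_code[h] for h in phh])
        self.ia = np.array([ind_code[i] for i in actor])
        self.ib = np.array([ind_code[i] for i in partner])
        self.household_of = np.zeros(len(self.individuals), dtype=int)
        for i, h in zip(np.r_[self.ia, self.ib], np.r_[self.ka, self.kb]):
            self.household_of[i] = h

        # (individual, foreign household) pairs: c uses the actor side,
        # d the partner side; the shared index set realizes the
        # (c_ik,l, d_l,ik) covariance pairing.
        cd_keys = sorted(
            {(i, h) for i, h in zip(self.ia, self.kb)}
            | {(j, h) for j, h in zip(self.ib, self.ka)}
        )
        cd_code = {key: c for c, key in enumerate(cd_keys)}
        self.cd_pairs = cd_keys
        self.cg = np.array([cd_code[(i, h)] for i, h in zip(self.ia, self.kb)])
        self.dg = np.array([cd_code[(j, h)] for j, h in zip(self.ib, self.ka)])

        hh_pairs = sorted({(min(k, l), max(k, l)) for k, l in zip(self.ka, self.kb)})
        hp_code = {p: c for c, p in enumerate(hh_pairs)}
        self.hh_pairs = hh_pairs
        self.hq = np.array(
            [hp_code[(min(k, l), max(k, l))] for k, l in zip(self.ka, self.kb)]
        )
        self.hslot = (self.ka > self.kb).astype(int)

        dyads = sorted({(min(i, j), max(i, j)) for i, j in zip(self.ia, self.ib)})
        dy_code = {p: c for c, p in enumerate(dyads)}
        self.dyads = dyads
        self.ud = np.array(
            [dy_code[(min(i, j), max(i, j))] for i, j in zip(self.ia, self.ib)]
        )

        self.n_rows = len(frame)
        self.n_households = len(self.households)
        self.n_individuals = len(self.individuals)
        self.n_cd_pairs = len(cd_keys)
        self.n_hh_pairs = len(hh_pairs)
        self.n_dyads = len(dyads)

    @classmethod
    def from_design(cls, design: DesignMatrix) -> "NetworkStructure":
        return cls(design.table)


@dataclass
class RandomEffectRealization:
    """One sampled set of all random-effect vectors for a community."""

    a2: np.ndarray  # (K,)
    b2: np.ndarray  # (K,)
    a1: np.ndarray  # (N,)
    b1: np.ndarray  # (N,)
    c: np.ndarray  # (P,) keyed by (individual, foreign household)
    d: np.ndarray  # (P,) same keying; d[p] = household giving to individual
    h: np.ndarray  # (Q, 2) unordered household pair x orientation slot
    u: np.ndarray  # (D,) unordered individual dyads

    def row_sum(self, s: NetworkStructure) -> np.ndarray:
        """Total random-effect contribution per directed dyad row."""
        return (
            self.a2[s.ka]
            + self.b2[s.kb]
            + self.a1[s.ia]
            + self.b1[s.ib]
            + self.c[s.cg]
            + self.d[s.dg]
            + self.h[s.hq, s.hslot]
            + self.u[s.ud]
        )


def _draw_bivariate(
    n: int, v1: float, v2: float, rho: float, label: str, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    _bivariate_cov(v1, v2, rho, label)  # validates PSD
    z1 = rng.standard_normal(n)
    z2 = rng.standard_normal(n)
    x1 = np.sqrt(v1) * z1
    x2 = np.sqrt(v2) * (rho * z1 + np.sqrt(max(1.0 - rho * rho, 0.0)) * z2)
    return x1, x2


def draw_random_effects(
    params: GSSRMParameters, structure: NetworkStructure, rng: np.random.Generator
) -> RandomEffectRealization:
    """Sample every random-effect block from its stated covariance."""
    a2, b2 = _draw_bivariate(
        structure.n_households, params.var_a2, params.var_b2, params.rho_a2b2, "(a2,b2)", rng
    )
    a1, b1 = _draw_bivariate(
        structure.n_individuals, params.var_a1, params.var_b1, params.rho_a1b1, "(a1,b1)", rng
    )
    c, d = _draw_bivariate(
        structure.n_cd_pairs, params.var_c, params.var_d, params.rho_cd, "(c,d)", rng
    )
    h0, h1 = _draw_bivariate(
        structure.n_hh_pairs, params.var_h, params.var_h, params.rho_hh, "(h,h)", rng
    )
    h = np.column_stack([h0, h1])
    u = (
        np.sqrt(params.var_u) * rng.standard_normal(structure.n_dyads)
        if params.var_u > 0
        else np.zeros(structure.n_dyads)
    )
    return RandomEffectRealization(a2=a2, b2=b2, a1=a1, b1=b1, c=c, d=d, h=h, u=u)


def latent_response(
    X: np.ndarray,
    beta: np.ndarray,
    effects: RandomEffectRealization,
    structure: NetworkStructure,
    residual: np.ndarray | None = None,
) -> np.ndarray:
    """Latent propensity per row: x beta + random effects (+ residual).

    ``residual`` is the per-row standard-normal disturbance; pass zeros
    to obtain the linear predictor itself.
    """
    if X.shape[0] != structure.n_rows:
        raise ValueError("design and structure row counts differ")
    if X.shape[1] != beta.shape[0]:
        raise ValueError("beta length does not match design columns")
    eta = X @ beta + effects.row_sum(structure)
    if residual is not None:
        if residual.shape[0] != structure.n_rows:
            raise ValueError("residual length does not match rows")
        eta = eta + residual
    return eta


@dataclass
class NetworkDataset:
    """Directed binary nominations with their covariate rows.

    ``table`` is the design table plus a ``y`` column; ``framing``
    records whether nominations are recipient-oriented (informants name
    who helps them; the informant is the partner j) or donor-oriented
    (informants name whom they help; the informant is the actor i).
    """

    table: pd.DataFrame
    columns: list[str]
    framing: str = "recipient"
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.framing not in ("recipient", "donor"):
            raise ValueError("framing must be 'recipient' or 'donor'")
        if "y" not in self.table.columns:
            raise ValueError("dataset table lacks the response column y")
        y = self.table["y"].to_numpy()
        if not np.isin(y, (0, 1)).all():
            raise ValueError("responses must be binary 0/1")

    @property
    def X(self) -> np.ndarray:
        return self.table[self.columns].to_numpy(dtype=float)

    @property
    def y(self) -> np.ndarray:
        return self.table["y"].to_numpy(dtype=int)

    def structure(self) -> NetworkStructure:
        return NetworkStructure(self.table)

    def nominations(self) -> pd.DataFrame:
        """Minimal edge list: ego, alter, framing, y."""
        return pd.DataFrame(
            {
                "ego": self.table["actor"],
                "alter": self.table["partner"],
                "framing": self.framing,
                "y": self.y,
            }
        )

    def to_csv(self, path) -> None:
        self.nominations().to_csv(path, index=False)


def simulate_network(
    design: DesignMatrix,
    params: GSSRMParameters,
    rng: np.random.Generator,
    framing: str = "recipient",
    effects: RandomEffectRealization | None = None,
) -> NetworkDataset:
    """Simulate binary nominations from the full latent-response model.

    Marginally over all effects the helping probability of a row is
    Phi(x beta / sqrt(1 + sum of active variances)).  The residual is
    drawn here and never stored: the returned dataset carries only the
    binary response.
    """
    structure = NetworkStructure.from_design(design)
    if effects is None:
        effects = draw_random_effects(params, structure, rng)
    beta = params.beta_vector(design.columns)
    residual = rng.standard_normal(structure.n_rows)
    ystar = latent_response(design.X, beta, effects, structure, residual)
    table = design.table.copy()
    table["y"] = (ystar >= 0.0).astype(int)
    return NetworkDataset(
        table=table,
        columns=list(design.columns),
        framing=framing,
        metadata=dict(design.metadata, model_id=design.model_id),
    )


def transpose_dataset(dataset: NetworkDataset) -> NetworkDataset:
    """Swap actor and partner roles, flipping the framing.

    The donor-oriented view of a recipient-oriented dataset: each row
    (i -> j, y) becomes (j -> i, y), and symmetric covariates carry
    over unchanged.  Only valid for intercept-only column sets or
    symmetric covariates; role-specific covariate columns are not
    remapped here.
    """
    table = dataset.table.copy()
    table[["actor", "partner"]] = table[["partner", "actor"]].to_numpy()
    table[["actor_household", "partner_household"]] = table[
        ["partner_household", "actor_household"]
    ].to_numpy()
    other = "donor" if dataset.framing == "recipient" else "recipient"
    return NetworkDataset(
        table=table,
        columns=list(dataset.columns),
        framing=other,
        metadata=dict(dataset.metadata),
    )
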