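"""Assortative-mating test and reproductive-fitness regressions.

The pair universe is every male x female combination among the adults.
Two generalized linear models describe reproduction over that universe:

* a logistic model of mating success (did the pair leave at least one
  sampled offspring?), fitted on ALL pairs:

  ``logit p_ij = b0 + b1·Oi + b2·Oj + b3·Oij + b4·Li + b5·Lj + b6·Si``

* a Poisson log-link model of offspring number, fitted on the successful
  pairs only, with the same design.

``Oi``/``Oj`` indicate west origin of the male/female (south = 0),
``Oij`` that both parents share an origin, ``Li``/``Lj`` are the size
covariates (total length in cm by default; weight/length in g·cm⁻¹ by
configuration), and ``Si`` marks sneaker males.  Fitting is maximum
likelihood via statsmodels GLM (IRLS) wrapped in the Model/Results idiom;
closed-form prediction helpers evaluate any coefficient vector.

The assortative-mating check is a 2x2 Yates-corrected chi-square on
distinct mating pairs classified by male origin x female origin (each
parental pair counted once regardless of family size; an
offspring-weighted variant is available).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps

from .genotype_data import Individual, Origin, Tactic
from .parentage import PedigreeAssignment

__all__ = [
    "COEF_NAMES",
    "build_pair_table",
    "MatingModelResults",
    "MatingSuccessModel",
    "OffspringCountModel",
    "predict_success_probability",
    "predict_offspring_count",
    "assortative_test",
    "AssortativeResult",
]

#: design columns, intercept first — seven coefficients total
COEF_NAMES = [
    "intercept",
    "male_origin",
    "female_origin",
    "same_origin",
    "male_size",
    "female_size",
    "sneaker_male",
]

COEF_DESCRIPTIONS = {
    "intercept": "Intercept",
    "male_origin": "Male origin (west = 1)",
    "female_origin": "Female origin (west = 1)",
    "same_origin": "Both parents of same origin",
    "male_size": "Male size covariate",
    "female_size": "Female size covariate",
    "sneaker_male": "Sneaker male",
}


def _size(ind: Individual, mode: str) -> float:
    if ind.total_length is None:
        raise ValueError(f"adult {ind.id} missing total length")
    if mode == "length":
        return float(ind.total_length)
    if mode == "weight_length":
        if ind.body_weight is None:
            raise ValueError(f"adult {ind.id} missing body weight")
        return float(ind.body_weight / ind.total_length)
    raise ValueError(f"unknown covariate_mode {mode!r}")


def build_pair_table(
    assignments: Sequence[PedigreeAssignment],
    registry: Mapping[str, Individual],
    covariate_mode: str = "length",
) -> pd.DataFrame:
    """One record per male x female combination with design covariates,
    success flag, and offspring count from the pedigree."""
    males = [
        i for i in registry.values()
        if i.is_adult and i.tactic in (Tactic.NESTING_MALE, Tactic.SNEAKER_MALE)
    ]
    females = [
        i for i in registry.values() if i.is_adult and i.tactic is Tactic.FEMALE
    ]
    missing = [
        i.id for i in males + females if i.total_length is None
    ]
    if missing:
        raise ValueError(f"adults missing size covariate: {missing}")
    counts: dict[tuple[str, str], int] = {}
    for a in assignments:
        if a.status != "assigned":
            continue
        key = (a.father_id, a.mother_id)
        counts[key] = counts.get(key, 0) + 1
    rows = []
    for m in males:
        o_i = 1 if m.origin is Origin.WEST else 0
        s_i = 1 if m.tactic is Tactic.SNEAKER_MALE else 0
        l_i = _size(m, covariate_mode)
        for f in females:
            o_j = 1 if f.origin is Origin.WEST else 0
            n_ij = counts.get((m.id, f.id), 0)
            rows.append(
                {
                    "male_id": m.id,
                    "female_id": f.id,
                    "male_origin": o_i,
                    "female_origin": o_j,
                    "same_origin": 1 if o_i == o_j else 0,
                    "male_size": l_i,
                    "female_size": _size(f, covariate_mode),
                    "sneaker_male": s_i,
                    "success": n_ij >= 1,
                    "n_offspring": n_ij,
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Model / Results
# ---------------------------------------------------------------------------

@dataclass
class MatingModelResults:
    """Coefficients, Wald standard errors and p-values of one mating GLM."""

    model_kind: str  # "logistic_success" | "poisson_count"
    params: pd.Series
    bse: pd.Series
    pvalues: pd.Series
    converged: bool
    n_records: int
    llf: float

    def summary(self) -> pd.DataFrame:
        """Report table: parameter, description, estimate, SE, p-value."""
        return pd.DataFrame(
            {
                "parameter": list(self.params.index),
                "description": [
                    COEF_DESCRIPTIONS[k] for k in self.params.index
                ],
                "estimate": self.params.values,
                "se": self.bse.values,
                "p_value": self.pvalues.values,
            }
        )

    def coef_vector(self) -> np.ndarray:
        return self.params.reindex(COEF_NAMES).to_numpy()


class _PairGLM:
    kind: str
    family: sm.families.Family

    def __init__(self, pairs: pd.DataFrame):
        self.pairs = pairs

    @classmethod
    def from_pairs(cls, pairs: pd.DataFrame):
        return cls(pairs)

    def _design(self, df: pd.DataFrame) -> pd.DataFrame:
        x = df[COEF_NAMES[1:]].astype(float)
        return sm.add_constant(x, has_constant="add").rename(
            columns={"const": "intercept"}
        )

    def _endog(self, df: pd.DataFrame) -> np.ndarray:
        raise NotImplementedError

    def _frame(self) -> pd.DataFrame:
        return self.pairs

    def fit(self, maxiter: int = 100, tol: float = 1e-8) -> MatingModelResults:
        df = self._frame()
        y = self._endog(df)
        x = self._design(df)
        glm = sm.GLM(y, x, family=self.family)
        res = glm.fit(maxiter=maxiter, tol=tol)
        return MatingModelResults(
            model_kind=self.kind,
            params=res.params,
            bse=res.bse,
            pvalues=res.pvalues,
            converged=bool(res.converged),
            n_records=len(df),
            llf=float(res.llf),
        )


class MatingSuccessModel(_PairGLM):
    """Logistic success/failure model over all male x female pairs."""

    kind = "logistic_success"

    @property
    def family(self):
        return sm.families.Binomial()

    def _endog(self, df):
        y = df["success"].astype(float).to_numpy()
        if y.min() == y.max():
            raise ValueError("both outcome classes required to fit")
        return y


class OffspringCountModel(_PairGLM):
    """Poisson log-link model of offspring number over successful pairs."""

    kind = "poisson_count"

    @property
    def family(self):
        return sm.families.Poisson()

    def _frame(self):
        df = self.pairs[self.pairs["success"]]
        if len(df) < len(COEF_NAMES) + 1:
            raise ValueError(
                f"{len(df)} successful pairs < {len(COEF_NAMES) + 1} required"
            )
        return df

    def _endog(self, df):
        return df["n_offspring"].astype(float).to_numpy()


# ---------------------------------------------------------------------------
# closed-form prediction
# ---------------------------------------------------------------------------

def _linear_predictor(coefs, o_i, o_j, o_ij, l_i, l_j, s_i) -> float:
    beta = np.asarray(
        coefs.coef_vector() if isinstance(coefs, MatingModelResults) else coefs,
        dtype=float,
    )
    if beta.shape != (7,):
        raise ValueError("expected 7 coefficients (intercept + 6 effects)")
    x = np.array([1.0, o_i, o_j, o_ij, l_i, l_j, s_i])
    return float(beta @ x)


def predict_success_probability(
    fit, o_i=0, o_j=0, o_ij=0, l_i=0.0, l_j=0.0, s_i=0
) -> float:
    """Inverse-logit of the success-model linear predictor; ``fit`` is a
    logistic :class:`MatingModelResults` or a bare 7-coefficient vector."""
    if isinstance(fit, MatingModelResults) and fit.model_kind != "logistic_success":
        raise ValueError("success prediction requires the logistic model")
    eta = _linear_predictor(fit, o_i, o_j, o_ij, l_i, l_j, s_i)
    return float(1.0 / (1.0 + np.exp(-eta)))


def predict_offspring_count(
    fit, o_i=0, o_j=0, o_ij=0, l_i=0.0, l_j=0.0, s_i=0
) -> float:
    """Expected offspring number exp(linear predictor) for the count model."""
    if isinstance(fit, MatingModelResults) and fit.model_kind != "poisson_count":
        raise ValueError("count prediction requires the Poisson model")
    return float(np.exp(_linear_predictor(fit, o_i, o_j, o_ij, l_i, l_j, s_i)))


# ---------------------------------------------------------------------------
# assortative mating
# ---------------------------------------------------------------------------

@dataclass
class AssortativeResult:
    chi2: float
    p_value: float
    table: pd.DataFrame  # male origin x female origin counts


def assortative_test(
    assignments: Sequence[PedigreeAssignment],
    registry: Mapping[str, Individual],
    weight_by_offspring: bool = False,
) -> AssortativeResult:
    """Yates-corrected 2x2 chi-square of mating-pair counts by male origin
    x female origin.

    Each distinct parental pair counts once (``weight_by_offspring=True``
    counts offspring instead).  The Yates term clamps |O - E| - 0.5 at
    zero so near-exact tables cannot inflate the statistic.
    """
    counts = np.zeros((2, 2))
    seen: set[tuple[str, str]] = set()
    for a in assignments:
        if a.status != "assigned":
            continue
        key = (a.father_id, a.mother_id)
        if not weight_by_offspring:
            if key in seen:
                continue
            seen.add(key)
        i = 1 if registry[a.father_id].origin is Origin.WEST else 0
        j = 1 if registry[a.mother_id].origin is Origin.WEST else 0
        counts[i, j] += 1
    table = pd.DataFrame(
        counts,
        index=pd.Index(["south_male", "west_male"]),
        columns=pd.Index(["south_female", "west_female"]),
    )
    if counts.sum() == 0 or (counts.sum(0) == 0).any() or (counts.sum(1) == 0).any():
        return AssortativeResult(float("nan"), float("nan"), table)
    expected = np.outer(counts.sum(1), counts.sum(0)) / counts.sum()
    adj = np.maximum(np.abs(counts - expected) - 0.5, 0.0)
    chi2 = float(np.sum(adj**2 / expected))
    p = float(sps.chi2.sf(chi2, df=1))
    return AssortativeResult(chi2, p, table)
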