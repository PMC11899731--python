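"""Synthetic cohorts with known ground truth.

The real venous-blood cohort this pipeline targets is access-restricted, so
every stage is exercised on generated data whose truth is known.  The
generator emulates the study conditions end to end:

* a 16-part composition drawn from a logistic-normal model whose latent
  precision matrix plants exactly three conditional-dependence edges
  (TCD4CM–TCD4O positive, TCD4CM–LYMPO negative, TCD8CM–TCD8O positive) and
  whose means are calibrated so median part proportions approximate the
  published subset medians (e.g. LYMPO ≈ 21%, TCD4N ≈ 20%);
* detection-limit zero inflation on the four smallest-median parts, at a
  rate giving roughly 46% of subjects at least one exact zero;
* covariates (age, sex, race, education, CMV serostatus) matching the
  published cohort marginals (median age 68, 57.4% women, 71.4% CMV
  reactive, ...);
* outcomes driven by a latent score from a known sparse zero-sum
  log-contrast coefficient vector: a continuous score, a binomial chronic
  disease index (0–8), a 5-level self-reported health rating, and a
  44-item deficit-accumulation frailty index with its 4-level category.

Everything is deterministic given (parameters, seed), and the ground truth
is serialized alongside every generated dataset.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit

from .tree import LEAVES, CompositionMatrix, CompositionTree, default_tree, replace_zeros
from .outcomes import categorize_frailty

__all__ = [
    "GroundTruth",
    "SyntheticCohort",
    "default_ground_truth",
    "generate_compositions",
    "generate_covariates",
    "generate_outcomes",
    "generate_cohort",
    "decompose_to_panel",
]

#: Median part proportions (% of total lymphocytes) used to calibrate the
#: latent means — the published cohort's subset medians.
PART_MEDIANS_PCT = {
    "TCD4N": 19.8, "TCD4CM": 17.3, "TCD4EM": 0.07, "TCD4TDEM": 0.53,
    "TCD4O": 6.46, "TCD8N": 2.79, "TCD8CM": 1.09, "TCD8EM": 0.11,
    "TCD8TDEM": 6.28, "TCD8O": 2.69, "TO": 4.06, "BN": 3.8,
    "BMIgD-": 0.53, "BMIgD+": 0.58, "BO": 0.52, "LYMPO": 21.1,
}

#: Planted conditional-dependence edges as (i, j, partial correlation).
PLANTED_EDGES = [
    ("TCD4CM", "TCD4O", +0.35),
    ("TCD4CM", "LYMPO", -0.35),
    ("TCD8CM", "TCD8O", +0.35),
]

#: Parts receiving detection-limit zeros (the four smallest medians).
ZERO_PARTS = ["TCD4EM", "TCD8EM", "BMIgD-", "BO"]

#: Default sparse zero-sum outcome coefficient *pattern* (signs mirror the
#: reported association pattern).  The pattern is rescaled at truth
#: construction so the composition signal attains the configured
#: signal-to-noise ratio; relative magnitudes are generator settings.
BETA_PATTERN = {
    "TCD4N": -0.20, "TCD4O": +0.12, "TCD8CM": +0.12, "TCD8O": -0.14,
    "LYMPO": +0.10,
}

#: Covariate effects on the latent health score (per-unit scales noted).
GAMMA_STAR = {
    "age": 0.030,          # per year, centred at 68
    "sex_female": 0.08,
    "race_black": 0.25,
    "race_hispanic": 0.00,
    "race_other": 0.05,
    "education_lower_secondary": -0.10,
    "education_upper_secondary": -0.30,
    "education_above_upper_secondary": -0.55,
    "cmv_reactive": 0.10,
}

#: Covariate marginal targets (published cohort Table-2-style shares).
COVARIATE_TARGETS = {
    "sex": {"men": 0.426, "female": 0.574},
    "race": {"white": 0.650, "black": 0.172, "hispanic": 0.146, "other": 0.032},
    "education": {
        "below_secondary": 0.087,
        "lower_secondary": 0.107,
        "upper_secondary": 0.301,
        "above_upper_secondary": 0.505,
    },
    "cmv": {"nonreactive": 0.286, "reactive": 0.714},
}


@dataclass
class GroundTruth:
    """All generator parameters: the truth against which recovery is judged."""

    precision: np.ndarray  # 16×16 latent precision (planted edges)
    mu: np.ndarray  # latent means (log scale)
    beta_star: pd.Series  # zero-sum outcome coefficients over the 16 leaves
    gamma_star: dict[str, float]
    noise_sd: float = 1.0
    zero_inflation_rate: float = 0.143
    zero_parts: tuple[str, ...] = tuple(ZERO_PARTS)
    leaves: tuple[str, ...] = tuple(LEAVES)

    def __post_init__(self) -> None:
        if abs(float(self.beta_star.sum())) > 1e-12:
            raise ValueError("beta_star must sum to zero exactly")
        w = np.linalg.eigvalsh(self.precision)
        if w.min() <= 0:
            raise ValueError("planted precision must be positive definite")

    def planted_signed_edges(self) -> dict[tuple[str, str], int]:
        idx = {p: k for k, p in enumerate(self.leaves)}
        out = {}
        d = np.sqrt(np.diag(self.precision))
        for i in range(len(self.leaves)):
            for j in range(i + 1, len(self.leaves)):
                om = self.precision[i, j]
                if abs(om) > 1e-10:
                    pcor = -om / (d[i] * d[j])
                    key = tuple(sorted((self.leaves[i], self.leaves[j])))
                    out[key] = int(np.sign(pcor))
        return out

    def to_json(self) -> str:
        return json.dumps(
            {
                "precision": self.precision.tolist(),
                "mu": self.mu.tolist(),
                "beta_star": self.beta_star.to_dict(),
                "gamma_star": self.gamma_star,
                "noise_sd": self.noise_sd,
                "zero_inflation_rate": self.zero_inflation_rate,
                "zero_parts": list(self.zero_parts),
                "leaves": list(self.leaves),
            },
            indent=2,
        )

    @classmethod
    def from_json(cls, text: str) -> "GroundTruth":
        d = json.loads(text)
        return cls(
            precision=np.array(d["precision"]),
            mu=np.array(d["mu"]),
            beta_star=pd.Series(d["beta_star"]).reindex(d["leaves"]).fillna(0.0),
            gamma_star=d["gamma_star"],
            noise_sd=d["noise_sd"],
            zero_inflation_rate=d["zero_inflation_rate"],
            zero_parts=tuple(d["zero_parts"]),
            leaves=tuple(d["leaves"]),
        )


def default_ground_truth(
    latent_sd: float = 0.7,
    small_part_sd: float = 1.2,
    zero_inflation_rate: float = 0.143,
    noise_sd: float = 1.0,
    snr: float = 2.0,
) -> GroundTruth:
    """The default study-condition truth.

    Latent log-scale spread is ``latent_sd`` for the abundant parts and
    ``small_part_sd`` for the four near-detection-limit parts (their
    published interquartile ranges span several fold-changes).  The planted
    partial correlations (±0.35) are the only entries above 0.2 in absolute
    value, so network-recovery truth is unambiguous.

    The zero-sum coefficient pattern is rescaled analytically so that the
    composition signal variance Var(ln(x)·β*) = β*ᵀΣβ* equals
    ``snr``·``noise_sd``² (the zero-sum constraint makes the closure term
    drop out, so the variance is exact, not simulated).  Pass ``snr=None``
    to keep the raw pattern magnitudes.
    """
    D = len(LEAVES)
    idx = {p: k for k, p in enumerate(LEAVES)}
    # unit-scale precision with planted partial correlations
    omega0 = np.eye(D)
    for a, b, rho in PLANTED_EDGES:
        omega0[idx[a], idx[b]] = omega0[idx[b], idx[a]] = -rho
    sd = np.full(D, latent_sd)
    for p in ZERO_PARTS:
        sd[idx[p]] = small_part_sd
    # diagonal scaling preserves the planted partial correlations
    S_inv = np.diag(1.0 / sd)
    precision = S_inv @ omega0 @ S_inv
    med = np.array([PART_MEDIANS_PCT[p] for p in LEAVES])
    # −σ²/2 correction: the closure denominator is driven by E[exp(latent)]
    # = exp(μ + σ²/2), so without it the high-variance (small) parts would
    # siphon share from the abundant parts and push medians off target
    mu = np.log(med / med.sum()) - 0.5 * sd**2
    beta = pd.Series(0.0, index=LEAVES)
    for k, v in BETA_PATTERN.items():
        beta[k] = v
    if snr is not None:
        cov = np.linalg.inv(precision)
        signal_var = float(beta.to_numpy() @ cov @ beta.to_numpy())
        beta *= np.sqrt(snr * noise_sd**2 / signal_var)
    return GroundTruth(
        precision=precision,
        mu=mu,
        beta_star=beta,
        gamma_star=dict(GAMMA_STAR),
        noise_sd=noise_sd,
        zero_inflation_rate=zero_inflation_rate,
    )


def generate_compositions(
    n: int,
    truth: GroundTruth | None = None,
    seed: int = 0,
) -> CompositionMatrix:
    """Draw n logistic-normal compositions with detection-limit zeros.

    Latent vectors come from MVN(mu, precision⁻¹); exponentiate-and-close
    maps them to the simplex.  For the designated small parts, values below
    the per-part empirical quantile at ``zero_inflation_rate`` are set to
    exact zero and the rows re-closed.
    """
    truth = truth or default_ground_truth()
    rng = np.random.default_rng(seed)
    cov = np.linalg.inv(truth.precision)
    latent = rng.multivariate_normal(truth.mu, cov, size=n, method="cholesky")
    x = np.exp(latent)
    x /= x.sum(axis=1, keepdims=True)
    rate = truth.zero_inflation_rate
    if rate > 0 and n > 1:
        cols = [list(truth.leaves).index(p) for p in truth.zero_parts]
        for j in cols:
            thresh = np.quantile(x[:, j], rate)
            x[x[:, j] < thresh, j] = 0.0
        x /= x.sum(axis=1, keepdims=True)
    df = pd.DataFrame(x, columns=list(truth.leaves))
    df.index.name = "subject_id"
    return CompositionMatrix(proportions=df)


def decompose_to_panel(
    comp: CompositionMatrix,
    tree: CompositionTree | None = None,
) -> pd.DataFrame:
    """Express a leaf composition as relative-to-parent percentages.

    Inverse of the percentage→composition conversion: internal-node totals
    are the sums of their descendant leaves and each measured node's
    percentage is its total over its parent's total × 100.  Only the 15
    measured columns are emitted (the "other" columns are derivable).  A
    zero parent makes a child's relative percentage undefined; it is emitted
    as 0.
    """
    tree = tree or default_tree()
    props = comp.proportions
    totals: dict[str, np.ndarray] = {"root": np.ones(len(props))}

    def node_total(name: str) -> np.ndarray:
        if name in totals:
            return totals[name]
        kids = tree.children(name)
        if not kids:
            t = props[name].to_numpy(dtype=float)
        else:
            t = np.sum([node_total(k) for k in kids], axis=0)
        totals[name] = t
        return t

    out = pd.DataFrame(index=props.index)
    for node in tree.nodes.values():
        if node.derived or node.name == "root":
            continue
        parent_t = node_total(node.parent)
        child_t = node_total(node.name)
        with np.errstate(divide="ignore", invalid="ignore"):
            pct = np.where(parent_t > 0, 100.0 * child_t / np.maximum(parent_t, 1e-300), 0.0)
        out[node.name] = pct
    return out


def _sample_categorical(rng, levels: dict[str, float], n: int) -> np.ndarray:
    names = list(levels)
    p = np.array([levels[k] for k in names], dtype=float)
    p = p / p.sum()
    return rng.choice(names, size=n, p=p)


def generate_covariates(n: int, seed: int = 0) -> pd.DataFrame:
    """Covariates with the published cohort's marginals.

    Age is 50 + lognormal(ln 18, 0.6012), which reproduces the published
    quartiles (62, 68, 77) exactly at the population level; the categorical
    covariates are independent draws at the published shares.
    """
    rng = np.random.default_rng(seed)
    age = 50.0 + np.exp(rng.normal(np.log(18.0), 0.6012, size=n))
    age = np.clip(age, 50.0, 105.0)
    return pd.DataFrame(
        {
            "age": np.round(age).astype(int),
            "sex": _sample_categorical(rng, COVARIATE_TARGETS["sex"], n),
            "race": _sample_categorical(rng, COVARIATE_TARGETS["race"], n),
            "education": _sample_categorical(rng, COVARIATE_TARGETS["education"], n),
            "cmv": _sample_categorical(rng, COVARIATE_TARGETS["cmv"], n),
        }
    )


def _covariate_score(cov: pd.DataFrame, gamma: dict[str, float]) -> np.ndarray:
    s = np.zeros(len(cov))
    s += gamma.get("age", 0.0) * (cov["age"].to_numpy(dtype=float) - 68.0)
    s += gamma.get("sex_female", 0.0) * (cov["sex"] == "female").to_numpy(dtype=float)
    for lvl in ("black", "hispanic", "other"):
        s += gamma.get(f"race_{lvl}", 0.0) * (cov["race"] == lvl).to_numpy(dtype=float)
    for lvl in ("lower_secondary", "upper_secondary", "above_upper_secondary"):
        s += gamma.get(f"education_{lvl}", 0.0) * (cov["education"] == lvl).to_numpy(dtype=float)
    s += gamma.get("cmv_reactive", 0.0) * (cov["cmv"] == "reactive").to_numpy(dtype=float)
    return s


# item "difficulties" of the 44 frailty deficits on the logit scale
_FRAILTY_OFFSETS = np.linspace(-3.0, 0.0, 44)
_SRH_CUTS = (-1.2, -0.4, 0.6, 1.5)


def generate_outcomes(
    comp: CompositionMatrix,
    covariates: pd.DataFrame,
    truth: GroundTruth | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Outcomes from the latent health score s = ln(x)·β* + covariates + noise.

    Compositions containing exact zeros receive column-minimum replacement
    before taking logs (the same rule the analysis pipeline applies).
    Emitted columns: ``score`` (continuous, Gaussian noise sd ``noise_sd``),
    ``cdi`` (binomial(8, logistic(−1.1 + s))), ``srh`` (1–5 by fixed
    thresholds on a noisy copy of s), ``frailty_index`` (mean of 44
    Bernoulli deficits with logit −3..0 + 0.9·s) and ``frailty_level``.
    """
    truth = truth or default_ground_truth()
    if len(comp.proportions) != len(covariates):
        raise ValueError("composition and covariates row counts differ")
    rng = np.random.default_rng(seed)
    work = comp
    if (comp.proportions.to_numpy() == 0).any():
        work = replace_zeros(comp)
    logx = np.log(work.proportions.to_numpy(dtype=float))
    beta = truth.beta_star.reindex(work.proportions.columns).fillna(0.0).to_numpy()
    s_comp = logx @ beta
    s_comp = s_comp - (truth.mu @ beta)  # centre at the latent-mean composition
    s = s_comp + _covariate_score(covariates, truth.gamma_star)

    score = s + rng.normal(0.0, truth.noise_sd, size=len(s))
    cdi = rng.binomial(8, expit(-1.1 + s))
    srh_latent = s + rng.normal(0.0, 0.8, size=len(s))
    srh = 1 + np.sum([srh_latent >= c for c in _SRH_CUTS], axis=0)
    p_items = expit(_FRAILTY_OFFSETS[None, :] + 0.9 * s[:, None])
    deficits = rng.random((len(s), 44)) < p_items
    findex = deficits.mean(axis=1)
    return pd.DataFrame(
        {
            "score": score,
            "cdi": cdi.astype(int),
            "srh": srh.astype(int),
            "frailty_index": findex,
            "frailty_level": categorize_frailty(findex),
        },
        index=comp.proportions.index,
    )


@dataclass
class SyntheticCohort:
    """A generated cohort plus the truth that produced it."""

    panel: pd.DataFrame  # 15 measured relative-to-parent percentages
    covariates: pd.DataFrame
    outcomes: pd.DataFrame
    composition: CompositionMatrix  # leaf truth (with zeros, pre-replacement)
    truth: GroundTruth
    seed: int

    def write(self, outdir) -> None:
        from pathlib import Path

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.panel.rename_axis("subject_id").to_csv(outdir / "panel.csv")
        self.covariates.rename_axis("subject_id").to_csv(outdir / "covariates.csv")
        self.outcomes.rename_axis("subject_id").to_csv(outdir / "outcomes.csv")
        self.composition.proportions.rename_axis("subject_id").to_csv(
            outdir / "composition.csv"
        )
        (outdir / "truth.json").write_text(self.truth.to_json())
        (outdir / "meta.json").write_text(
            json.dumps({"n": len(self.panel), "seed": self.seed}, indent=2)
        )


def generate_cohort(
    n: int,
    truth: GroundTruth | None = None,
    seed: int = 0,
) -> SyntheticCohort:
    """Full cohort: percentage panel, covariates, outcomes and truth.

    Sub-stage seeds are derived deterministically from ``seed`` so the three
    random stages (composition, covariates, outcomes) are independent.
    """
    truth = truth or default_ground_truth()
    ss = np.random.SeedSequence(seed).spawn(3)
    sub = [int(s.generate_state(1)[0] % (2**31 - 1)) for s in ss]
    comp = generate_compositions(n, truth, seed=sub[0])
    cov = generate_covariates(n, seed=sub[1])
    cov.index = comp.proportions.index
    out = generate_outcomes(comp, cov, truth, seed=sub[2])
    panel = decompose_to_panel(comp)
    return SyntheticCohort(
        panel=panel, covariates=cov, outcomes=out,
        composition=comp, truth=truth, seed=seed,
    )
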