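"""Synthetic EVT cohort generator.

Produces patient-level tables (sex, 71 BCC columns, recanalization outcome,
stroke etiology, cardiovascular covariates) plus free-text radiology reports,
together with the planted ground truth used by recovery tests.

BCC columns are drawn from a block-structured multivariate normal: variables
within a cluster share a latent factor (within-block correlation
``rho_within``), all variables share a global factor (between-block
correlation ``rho_between``).  Outcomes are drawn from logistic
(recanalization) and multinomial-logit (etiology) models on standardized
cluster means with sex-specific coefficients.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import ETIOLOGY_CLASSES, ConfigError, GeneratorConfig

TICI_GRADES = ("0", "1", "2a", "2b", "2c", "3")
FAILURE_GRADES = ("0", "1", "2a", "2b", "2c")


@dataclass
class PlantedTruth:
    """Ground truth planted in a generated cohort (for recovery tests)."""

    cluster_assignment: dict[str, int]  # variable name -> cluster id (0-based)
    cluster_sizes: list[int]
    sex_shift_vars: dict[int, float]
    informative_clusters: dict[str, dict[int, float]]
    etiology_clusters: dict[str, dict[int, tuple[float, float]]]
    report_labels: dict[str, str] = field(default_factory=dict)  # patient_id -> status

    def assignment_vector(self) -> np.ndarray:
        names = sorted(self.cluster_assignment, key=lambda s: int(s.split("_")[1]))
        return np.array([self.cluster_assignment[v] for v in names])

    def to_json(self, path: str) -> None:
        payload = {
            "cluster_assignment": self.cluster_assignment,
            "cluster_sizes": self.cluster_sizes,
            "sex_shift_vars": {str(k): v for k, v in self.sex_shift_vars.items()},
            "informative_clusters": {
                g: {str(k): v for k, v in d.items()} for g, d in self.informative_clusters.items()
            },
            "etiology_clusters": {
                g: {str(k): list(v) for k, v in d.items()} for g, d in self.etiology_clusters.items()
            },
            "report_labels": self.report_labels,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)


def bcc_name(i: int) -> str:
    return f"bcc_{i + 1:03d}"


def bcc_columns(n_bcc: int) -> list[str]:
    return [bcc_name(i) for i in range(n_bcc)]


def default_cluster_sizes(n_bcc: int, n_clusters: int) -> list[int]:
    """Distribute ``n_bcc`` variables over ``n_clusters`` blocks.

    With the defaults (71 variables, 58 clusters) this yields 45 singletons
    and 13 blocks of size 2, matching a mostly fine-grained clustering.
    Extra variables beyond ``n_clusters`` are added one at a time to the
    first clusters.
    """
    if n_clusters > n_bcc:
        raise ConfigError("n_clusters must not exceed n_bcc")
    sizes = [1] * n_clusters
    for i in range(n_bcc - n_clusters):
        sizes[i % n_clusters] += 1
    return sizes


def _assignment_from_sizes(sizes: list[int]) -> np.ndarray:
    out = np.empty(sum(sizes), dtype=int)
    pos = 0
    for cid, m in enumerate(sizes):
        out[pos : pos + m] = cid
        pos += m
    return out


def _sample_block_normal(
    rng: np.random.Generator,
    n: int,
    assignment: np.ndarray,
    rho_within: float,
    rho_between: float,
) -> np.ndarray:
    """Draw n x p standard-normal data with the block correlation structure.

    Factor construction: sqrt(rho_b) * global + sqrt(rho_w - rho_b) * block
    + sqrt(1 - rho_w) * idiosyncratic, which gives unit marginal variance,
    within-block correlation rho_w and between-block correlation rho_b.
    """
    p = assignment.size
    k = int(assignment.max()) + 1
    g = rng.standard_normal((n, 1))
    b = rng.standard_normal((n, k))
    e = rng.standard_normal((n, p))
    return (
        np.sqrt(rho_between) * g
        + np.sqrt(rho_within - rho_between) * b[:, assignment]
        + np.sqrt(1.0 - rho_within) * e
    )


def cluster_means(X: np.ndarray, assignment: np.ndarray, standardize: bool = True,
                  rho_within: float | None = None) -> np.ndarray:
    """Per-patient mean of member columns for each cluster.

    When ``standardize`` and ``rho_within`` are given, divides by the
    theoretical SD of a mean of m unit-variance members with pairwise
    correlation rho_within, so planted coefficients are per SD.
    """
    k = int(assignment.max()) + 1
    reps = np.empty((X.shape[0], k))
    for c in range(k):
        cols = np.flatnonzero(assignment == c)
        reps[:, c] = X[:, cols].mean(axis=1)
        if standardize and rho_within is not None:
            m = cols.size
            sd = np.sqrt((1.0 + (m - 1) * rho_within) / m)
            reps[:, c] /= sd
    return reps


def _coef_vector(groups: dict[str, dict[int, float]], sex: str, k: int) -> np.ndarray:
    beta = np.zeros(k)
    for c, v in groups.get("shared", {}).items():
        beta[c] += v
    key = "female_only" if sex == "F" else "male_only"
    for c, v in groups.get(key, {}).items():
        beta[c] += v
    return beta


def _etiology_coefs(groups: dict[str, dict[int, tuple[float, float]]], sex: str,
                    k: int) -> np.ndarray:
    # k x 2 matrix of (CE, LAA) log-odds relative to UND
    beta = np.zeros((k, 2))
    for c, v in groups.get("shared", {}).items():
        beta[c] += np.asarray(v, dtype=float)
    key = "female_only" if sex == "F" else "male_only"
    for c, v in groups.get(key, {}).items():
        beta[c] += np.asarray(v, dtype=float)
    return beta


def generate_cohort(config: GeneratorConfig) -> tuple[pd.DataFrame, PlantedTruth]:
    """Generate a patient-level cohort with planted structure.

    Returns the cohort as a DataFrame (one row per patient) and the planted
    truth.  Deterministic given ``config.seed``.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_female + config.n_male
    sizes = default_cluster_sizes(config.n_bcc, config.n_clusters)
    assignment = _assignment_from_sizes(sizes)
    sex = np.array(["F"] * config.n_female + ["M"] * config.n_male)

    X = _sample_block_normal(rng, n, assignment, config.rho_within, config.rho_between)
    # Sex shifts in SD units: women get +delta, men are the reference.
    female = sex == "F"
    for v, delta in config.sex_shift_vars.items():
        X[female, v] += delta

    reps = cluster_means(X, assignment, standardize=True, rho_within=config.rho_within)

    # Recanalization: logistic on standardized cluster means, sex-specific.
    eta = np.full(n, config.success_intercept)
    for s in ("F", "M"):
        mask = sex == s
        beta = _coef_vector(config.informative_clusters, s, config.n_clusters)
        eta[mask] += reps[mask] @ beta
    p_success = 1.0 / (1.0 + np.exp(-eta))
    success = rng.random(n) < p_success

    # Etiology: multinomial logit (CE, LAA vs UND) with baseline intercepts
    # matching the configured marginals.
    m_ce, m_laa, m_und = config.etiology_marginals
    intercepts = np.array([np.log(m_ce / m_und), np.log(m_laa / m_und)])
    eta_et = np.tile(intercepts, (n, 1))
    for s in ("F", "M"):
        mask = sex == s
        bet = _etiology_coefs(config.etiology_clusters, s, config.n_clusters)
        eta_et[mask] += reps[mask] @ bet
    logits = np.concatenate([eta_et, np.zeros((n, 1))], axis=1)
    logits -= logits.max(axis=1, keepdims=True)
    probs = np.exp(logits)
    probs /= probs.sum(axis=1, keepdims=True)
    u = rng.random(n)
    cum = probs.cumsum(axis=1)
    etiology_idx = (u[:, None] > cum).sum(axis=1)
    etiology = np.array(ETIOLOGY_CLASSES)[etiology_idx]

    if config.marginal == "lognormal":
        X = np.exp(X)

    # MCAR missingness on BCCs.
    if config.missing_rate > 0:
        mask = rng.random(X.shape) < config.missing_rate
        X = np.where(mask, np.nan, X)

    cols = bcc_columns(config.n_bcc)
    df = pd.DataFrame(X, columns=cols)
    df.insert(0, "patient_id", [f"P{i + 1:04d}" for i in range(n)])
    df.insert(1, "sex", sex)
    df["recanalization"] = np.where(success, "success", "failure")
    df["etiology"] = etiology
    for name, prev in config.covariate_prevalences.items():
        df[name] = (rng.random(n) < prev).astype(int)
    df["ivt"] = (rng.random(n) < config.ivt_prevalence).astype(int)

    truth = PlantedTruth(
        cluster_assignment={bcc_name(i): int(assignment[i]) for i in range(config.n_bcc)},
        cluster_sizes=sizes,
        sex_shift_vars=dict(config.sex_shift_vars),
        informative_clusters={g: dict(d) for g, d in config.informative_clusters.items()},
        etiology_clusters={g: dict(d) for g, d in config.etiology_clusters.items()},
    )
    return df, truth


_REPORT_TEMPLATES = (
    "CT angiography showed M1 occlusion. Thrombectomy performed. Final result: {m} {g}.",
    "EVT with stent retriever, two passes. {m} {g} at end of procedure.",
    "Groin puncture 14:32. Aspiration thrombectomy. Final {m}: {g}.",
    "Procedure report: successful access, final angiographic result {m}-{g}.",
)
_NO_MENTION_TEXT = (
    "Thrombectomy attempted; final angiographic result described narratively, "
    "reperfusion grade not stated."
)


def _grade_for(success: bool, rng: np.random.Generator) -> str:
    if success:
        return "3"
    return FAILURE_GRADES[rng.integers(len(FAILURE_GRADES))]


def generate_reports(
    cohort: pd.DataFrame, config: GeneratorConfig
) -> tuple[list[dict[str, str]], dict[str, str]]:
    """Generate one radiology-report text per patient.

    Each report carries a TICI grade consistent with the patient's
    recanalization label with probability ``1 - label_noise``; configured
    fractions carry no mention (``none_rate``) or two conflicting mentions
    (``conflict_rate``), exercising the manual-label triage downstream.

    Returns the reports (list of ``{"patient_id", "text"}``) and a map
    patient_id -> planted report status (``clean``/``noisy``/``none``/
    ``conflict``).
    """
    config.validate()
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 911]))
    mentions = ("TICI", "eTICI", "mTICI")
    reports: list[dict[str, str]] = []
    statuses: dict[str, str] = {}
    for pid, recan in zip(cohort["patient_id"], cohort["recanalization"]):
        success = recan == "success"
        u = rng.random()
        template = _REPORT_TEMPLATES[rng.integers(len(_REPORT_TEMPLATES))]
        mention = mentions[rng.integers(len(mentions))]
        if u < config.none_rate:
            text = _NO_MENTION_TEXT
            status = "none"
        elif u < config.none_rate + config.conflict_rate:
            g1 = _grade_for(success, rng)
            others = [g for g in TICI_GRADES if g != g1]
            g2 = others[rng.integers(len(others))]
            text = (
                f"Initially {mention} {g1} after first pass. "
                f"Final result after further passes: {mention} {g2}."
            )
            status = "conflict"
        else:
            noisy = rng.random() < config.label_noise
            grade = _grade_for(not success if noisy else success, rng)
            text = template.format(m=mention, g=grade)
            status = "noisy" if noisy else "clean"
        reports.append({"patient_id": str(pid), "text": text})
        statuses[str(pid)] = status
    return reports, statuses


def write_cohort_csv(cohort: pd.DataFrame, path: str) -> None:
    cohort.to_csv(path, index=False)


def read_cohort_csv(path: str) -> pd.DataFrame:
    return pd.read_csv(path, dtype={"patient_id": str})


def write_reports_jsonl(reports: list[dict[str, str]], path: str) -> None:
    with open(path, "w") as fh:
        for rec in reports:
            fh.write(json.dumps(rec) + "\n")


def read_reports_jsonl(path: str) -> list[dict[str, str]]:
    with open(path) as fh:
        return [json.loads(line) for line in fh if line.strip()]
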