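"""Cohort containers, synthetic-cohort generation, CSV I/O and splitting.

The package models a perioperative sepsis cohort: one row of preoperative
static indicators per patient (labs plus age, 20 by default) and a block of
intraoperative monitoring series (heart rate, systolic/diastolic pressure,
oxygen saturation, central venous pressure). The real cohort this design
targets is private, so :func:`generate_synthetic_cohort` emulates its shape
— ~1,500 patients with ~5% sepsis — with a *known* planted structure: a
small set of static indicators and the dispersion (not the level) of one
monitoring signal drive the outcome, reflecting the clinical premise that
strongly fluctuating vital signs flag patients at risk.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.model_selection import train_test_split

logger = logging.getLogger(__name__)

#: Preoperative indicator abbreviations, in canonical column order.
STATIC_FEATURE_NAMES: tuple[str, ...] = (
    "5-NT", "Cl", "GFR", "GLT", "Crea", "CG", "K", "Age", "Na", "TTT-U",
    "AFU", "Urea", "Fbg", "AST", "Cys-C", "P", "FDP", "D-Dimer", "Osm", "PLT#",
)

#: Intraoperative monitoring signals, fixed order.
SIGNAL_NAMES: tuple[str, ...] = ("HR", "SBP", "DBP", "SPO2", "CVP")

# plausible adult perioperative scales (location, spread) per static indicator,
# used only to place synthetic values on a clinical-looking scale
_STATIC_SCALES = {
    "5-NT": (5.0, 2.5), "Cl": (103.0, 3.0), "GFR": (95.0, 20.0),
    "GLT": (28.0, 15.0), "Crea": (75.0, 20.0), "CG": (2.0, 1.2),
    "K": (4.1, 0.4), "Age": (52.0, 14.0), "Na": (140.0, 3.0),
    "TTT-U": (0.3, 0.5), "AFU": (22.0, 6.0), "Urea": (5.4, 1.6),
    "Fbg": (3.1, 0.8), "AST": (26.0, 12.0), "Cys-C": (0.9, 0.25),
    "P": (1.1, 0.2), "FDP": (2.5, 1.5), "D-Dimer": (0.6, 0.5),
    "Osm": (292.0, 6.0), "PLT#": (220.0, 60.0),
}

# AR(1) anchors for the monitoring signals: (physiologic mean, innovation sd)
_SIGNAL_SCALES = {
    "HR": (80.0, 3.0), "SBP": (120.0, 5.0), "DBP": (70.0, 4.0),
    "SPO2": (98.0, 0.6), "CVP": (8.0, 1.0),
}
_AR_COEF = 0.8


@dataclass
class CohortTable:
    """Static preoperative table: one row per patient plus the sepsis label."""

    patient_id: list[str]
    X_s: np.ndarray           # (n, p_s)
    y: np.ndarray             # (n,) in {0, 1}
    feature_names: list[str] = field(default_factory=lambda: list(STATIC_FEATURE_NAMES))

    def __post_init__(self) -> None:
        self.X_s = np.asarray(self.X_s, dtype=float)
        self.y = np.asarray(self.y)
        if self.X_s.shape[0] != len(self.y) or self.X_s.shape[0] != len(self.patient_id):
            raise ValueError("patient_id, X_s and y must agree in length")
        if np.isnan(self.X_s).any():
            raise ValueError("X_s contains NaN; impute before constructing")
        if not np.isin(self.y, (0, 1)).all():
            raise ValueError("labels must be binary 0/1")

    @property
    def n(self) -> int:
        return len(self.y)


@dataclass
class TemporalSignals:
    """Intraoperative monitoring series, one (signals x time) block per patient."""

    patient_id: list[str]
    X_v: np.ndarray           # (n, c, T)
    signal_names: list[str] = field(default_factory=lambda: list(SIGNAL_NAMES))
    lengths: np.ndarray | None = None   # true series length per patient, if padded

    def __post_init__(self) -> None:
        self.X_v = np.asarray(self.X_v, dtype=float)
        if self.X_v.ndim != 3:
            raise ValueError("X_v must be (n_patients, n_signals, T)")
        if self.X_v.shape[2] < 1:
            raise ValueError("at least one time step required")
        if self.X_v.shape[1] != len(self.signal_names):
            raise ValueError("signal_names must match the signal axis")
        if self.lengths is not None:
            self.lengths = np.asarray(self.lengths, dtype=int)

    @property
    def n(self) -> int:
        return self.X_v.shape[0]


@dataclass
class SynthConfig:
    """Knobs of the synthetic cohort generator.

    Defaults reproduce the target cohort shape: 1,538 patients with 82
    sepsis cases, 20 static indicators, 5 monitoring signals. Five features
    of the eventual 30-dim feature vector are informative: four static
    indicators plus the standard deviation of the first monitoring signal
    (heart-rate variability, ``HR_S``).
    """

    n: int = 1538
    positive_count: int = 82
    p_s: int = 20
    c: int = 5
    T: int = 32
    informative_static: tuple[int, ...] = (0, 7, 8, 12)
    informative_signal: int = 0
    effect_size: float = 2.0
    noise_sd: float = 1.0
    seed: int = 0

    def validate(self) -> None:
        if self.n < 1 or not (0 <= self.positive_count <= self.n):
            raise ValueError("need 0 <= positive_count <= n, n >= 1")
        if self.p_s < 1 or self.c < 1 or self.T < 1:
            raise ValueError("p_s, c and T must be positive")
        if any(not 0 <= j < self.p_s for j in self.informative_static):
            raise ValueError("informative_static index out of range")
        if not 0 <= self.informative_signal < self.c:
            raise ValueError("informative_signal index out of range")
        if self.effect_size < 0:
            raise ValueError("effect_size must be nonnegative")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")


def _feature_names(p_s: int) -> list[str]:
    names = list(STATIC_FEATURE_NAMES[:p_s])
    names += [f"X{i+1}" for i in range(len(names), p_s)]
    return names


def _signal_names(c: int) -> list[str]:
    names = list(SIGNAL_NAMES[:c])
    names += [f"SIG{i+1}" for i in range(len(names), c)]
    return names


def generate_synthetic_cohort(cfg: SynthConfig) -> tuple[CohortTable, TemporalSignals]:
    """Generate a cohort with planted outcome structure.

    The latent risk score is linear-logistic in the standardized informative
    static indicators plus the (standardized) realized dispersion of the
    informative monitoring signal, with additive Gaussian noise of sd
    ``noise_sd``. The ``positive_count`` patients with the highest risk are
    labelled positive, so class counts are exact by construction.

    Monitoring series are AR(1) fluctuations around each signal's
    physiologic mean; per-patient heterogeneity in the innovation scale of
    the informative signal provides the dispersion the risk score reads,
    so high-variability patients are (stochastically) the cases.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    names = _feature_names(cfg.p_s)
    sig_names = _signal_names(cfg.c)

    # static block: latent z-scores mapped onto clinical-looking scales
    Z = rng.standard_normal((cfg.n, cfg.p_s))
    X_s = np.empty_like(Z)
    for j, name in enumerate(names):
        loc, scale = _STATIC_SCALES.get(name, (0.0, 1.0))
        X_s[:, j] = loc + scale * Z[:, j]

    # per-patient innovation-scale multiplier on the informative signal:
    # lognormal heterogeneity in vital-sign volatility
    g = rng.lognormal(mean=0.0, sigma=0.5, size=cfg.n)

    X_v = np.empty((cfg.n, cfg.c, cfg.T))
    innov = rng.standard_normal((cfg.n, cfg.c, cfg.T))
    for k, sname in enumerate(sig_names):
        mu, sd = _SIGNAL_SCALES.get(sname, (0.0, 1.0))
        scale = sd * (g if k == cfg.informative_signal else np.ones(cfg.n))
        x = np.zeros((cfg.n, cfg.T))
        prev = np.zeros(cfg.n)
        for t in range(cfg.T):
            prev = _AR_COEF * prev + scale * innov[:, k, t]
            x[:, t] = prev
        X_v[:, k, :] = mu + x

    # realized dispersion of the informative signal (population sd over time)
    disp = X_v[:, cfg.informative_signal, :].std(axis=1)
    disp_z = (disp - disp.mean()) / disp.std() if disp.std() > 0 else disp * 0.0

    k_inf = len(cfg.informative_static)
    static_term = (Z[:, list(cfg.informative_static)].sum(axis=1) / np.sqrt(k_inf)
                   if k_inf else np.zeros(cfg.n))
    risk = cfg.effect_size * static_term + cfg.effect_size * disp_z \
        + cfg.noise_sd * rng.standard_normal(cfg.n)

    y = np.zeros(cfg.n, dtype=int)
    if cfg.positive_count:
        # highest-risk patients become the cases: class counts are exact
        order = np.argsort(risk, kind="stable")
        y[order[-cfg.positive_count:]] = 1

    ids = [f"P{i+1:05d}" for i in range(cfg.n)]
    cohort = CohortTable(ids, X_s, y, feature_names=names)
    signals = TemporalSignals(list(ids), X_v, signal_names=sig_names)
    return cohort, signals


def true_risk_score(cfg: SynthConfig) -> np.ndarray:
    """Regenerate the planted structural risk score, without label noise.

    This is the informative-feature contribution (standardized informative
    statics plus standardized dispersion of the informative signal),
    unscaled by ``effect_size``. At ``effect_size=0`` the labels are driven
    by noise alone, so this score discriminates them at chance level.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    Z = rng.standard_normal((cfg.n, cfg.p_s))
    g = rng.lognormal(mean=0.0, sigma=0.5, size=cfg.n)
    innov = rng.standard_normal((cfg.n, cfg.c, cfg.T))
    sig_names = _signal_names(cfg.c)
    k = cfg.informative_signal
    mu, sd = _SIGNAL_SCALES.get(sig_names[k], (0.0, 1.0))
    x = np.zeros((cfg.n, cfg.T))
    prev = np.zeros(cfg.n)
    for t in range(cfg.T):
        prev = _AR_COEF * prev + sd * g * innov[:, k, t]
        x[:, t] = prev
    disp = (mu + x).std(axis=1)
    disp_z = (disp - disp.mean()) / disp.std() if disp.std() > 0 else disp * 0.0
    k_inf = len(cfg.informative_static)
    static_term = (Z[:, list(cfg.informative_static)].sum(axis=1) / np.sqrt(k_inf)
                   if k_inf else np.zeros(cfg.n))
    return static_term + disp_z


def informative_feature_indices(cfg: SynthConfig) -> list[int]:
    """Planted informative columns of the combined 30-dim feature vector.

    Layout: static block (p_s), then per-signal means (c), then per-signal
    standard deviations (c); the informative signal contributes its sd.
    """
    return sorted(list(cfg.informative_static)
                  + [cfg.p_s + cfg.c + cfg.informative_signal])


# --------------------------------------------------------------------- I/O
class CohortLoadError(ValueError):
    """Raised on malformed cohort files, with row/ID context."""


def save_cohort(cohort: CohortTable, signals: TemporalSignals,
                static_path, temporal_path) -> None:
    """Write the static table and long-format temporal CSVs."""
    df = pd.DataFrame(cohort.X_s, columns=cohort.feature_names)
    df.insert(0, "patient_id", cohort.patient_id)
    df["label"] = cohort.y
    df.to_csv(static_path, index=False, float_format="%.17g")

    n, c, T = signals.X_v.shape
    lengths = signals.lengths if signals.lengths is not None else np.full(n, T)
    frames = []
    for i, pid in enumerate(signals.patient_id):
        L = int(lengths[i])
        block = pd.DataFrame(signals.X_v[i, :, :L].T, columns=signals.signal_names)
        block.insert(0, "time_index", np.arange(L))
        block.insert(0, "patient_id", pid)
        frames.append(block)
    pd.concat(frames, ignore_index=True).to_csv(temporal_path, index=False,
                                                float_format="%.17g")


def load_cohort(static_path, temporal_path, *,
                on_missing: str = "error") -> tuple[CohortTable, TemporalSignals]:
    """Load a cohort from a static CSV and a long-format temporal CSV.

    Parameters
    ----------
    on_missing
        ``"error"`` (default) rejects patients present in only one file,
        naming them; ``"drop"`` keeps the intersection.

    Missing numeric cells in the static table are imputed with the column
    median (logged). Variable-length series are right-padded with their last
    observation; true lengths are kept so statistics use observed samples only.
    """
    static_path, temporal_path = Path(static_path), Path(temporal_path)
    try:
        sdf = pd.read_csv(static_path, float_precision="round_trip")
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise CohortLoadError(f"cannot parse {static_path}: {exc}") from exc
    if "patient_id" not in sdf.columns or "label" not in sdf.columns:
        raise CohortLoadError(
            f"{static_path}: header must contain 'patient_id' and 'label'")
    feature_cols = [c for c in sdf.columns if c not in ("patient_id", "label")]
    if not feature_cols:
        raise CohortLoadError(f"{static_path}: no feature columns found")
    if sdf["patient_id"].duplicated().any():
        dup = sdf.loc[sdf["patient_id"].duplicated(), "patient_id"].iloc[0]
        raise CohortLoadError(f"{static_path}: duplicate patient_id {dup!r}")

    feats = sdf[feature_cols].apply(pd.to_numeric, errors="coerce")
    bad = feats.isna() & sdf[feature_cols].notna()
    if bad.any().any():
        r, c = np.argwhere(bad.values)[0]
        raise CohortLoadError(
            f"{static_path}: non-numeric cell at row {r + 2}, "
            f"column {feature_cols[c]!r}")
    for col in feature_cols:
        if feats[col].isna().any():
            med = feats[col].median()
            n_imp = int(feats[col].isna().sum())
            logger.warning("imputing %d missing %r cells with median %.6g",
                           n_imp, col, med)
            feats[col] = feats[col].fillna(med)

    tdf = pd.read_csv(temporal_path, float_precision="round_trip")
    need = {"patient_id", "time_index"}
    if not need.issubset(tdf.columns):
        raise CohortLoadError(
            f"{temporal_path}: header must contain patient_id and time_index")
    signal_cols = [c for c in tdf.columns if c not in need]
    if tdf.duplicated(subset=["patient_id", "time_index"]).any():
        row = tdf[tdf.duplicated(subset=["patient_id", "time_index"])].iloc[0]
        raise CohortLoadError(
            f"{temporal_path}: duplicate (patient_id, time_index) = "
            f"({row['patient_id']!r}, {row['time_index']})")

    static_ids = list(sdf["patient_id"].astype(str))
    temporal_ids = set(tdf["patient_id"].astype(str))
    missing_t = [p for p in static_ids if p not in temporal_ids]
    extra_t = sorted(temporal_ids - set(static_ids))
    if (missing_t or extra_t) and on_missing == "error":
        who = (missing_t + extra_t)[0]
        raise CohortLoadError(
            f"patient {who!r} present in only one of the two files "
            f"(use on_missing='drop' to keep the intersection)")
    keep = [p for p in static_ids if p in temporal_ids]
    sdf = sdf.set_index(sdf["patient_id"].astype(str)).loc[keep]
    feats = feats.set_index(np.array(static_ids)).loc[keep]

    grouped = {str(pid): blk.sort_values("time_index")
               for pid, blk in tdf.groupby("patient_id", sort=False)}
    lengths = np.array([len(grouped[p]) for p in keep])
    T = int(lengths.max())
    X_v = np.empty((len(keep), len(signal_cols), T))
    for i, pid in enumerate(keep):
        block = grouped[pid][signal_cols].to_numpy(dtype=float).T  # (c, L)
        L = block.shape[1]
        X_v[i, :, :L] = block
        if L < T:   # pad by holding the last observation
            X_v[i, :, L:] = block[:, -1:]

    cohort = CohortTable(keep, feats.to_numpy(dtype=float),
                         sdf["label"].to_numpy(dtype=int),
                         feature_names=feature_cols)
    signals = TemporalSignals(
        list(keep), X_v, signal_names=signal_cols,
        lengths=lengths if (lengths != T).any() else None)
    return cohort, signals


def split_train_test(cohort: CohortTable, signals: TemporalSignals,
                     train_frac: float = 0.8, seed: int = 0, *,
                     stratify: bool = True):
    """Random (stratified by default) patient-level split.

    Train size is ``floor(train_frac * n)``, matching scikit-learn's
    convention; returns ``((cohort_tr, signals_tr), (cohort_te, signals_te))``.
    """
    if not 0.0 < train_frac < 1.0:
        raise ValueError("train_frac must be in (0, 1)")
    if cohort.n < 2:
        raise ValueError("need at least two patients to split")
    idx = np.arange(cohort.n)
    strat = cohort.y if stratify else None
    tr, te = train_test_split(idx, train_size=train_frac, random_state=seed,
                              stratify=strat)
    tr, te = np.sort(tr), np.sort(te)

    def take(sel):
        lens = signals.lengths[sel] if signals.lengths is not None else None
        return (CohortTable([cohort.patient_id[i] for i in sel],
                            cohort.X_s[sel], cohort.y[sel],
                            feature_names=list(cohort.feature_names)),
                TemporalSignals([signals.patient_id[i] for i in sel],
                                signals.X_v[sel],
                                signal_names=list(signals.signal_names),
                                lengths=lens))

    return take(tr), take(te)
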