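"""TSS-weighted ensemble suitability protocol.

The protocol: sample one pseudo-absence per presence from the background
(prevalence 0.5), split presences and pseudo-absences 75/25 into calibration
and evaluation, fit every niche model on the calibration split, pick each
model's binarization threshold from its ROC curve (maximizing sensitivity +
specificity, i.e. the True Skill Statistic) on the evaluation split, and
repeat over many randomizations. Per (method x climate scenario) the binary
predictions are stacked into a frequency map; the frequency maps are then
averaged, weighted by each map's mean evaluation TSS, into a single consensus
suitability surface in [0, 1] — 0 where no model ever predicts presence, 1
where all always do. Future scenarios reuse the fitted replicates and their
thresholds, re-projected onto the future layers (no re-fitting).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator

from .grids import EnvStack
from .niche import PRESENCE_ABSENCE_MODELS, make_model

__all__ = [
    "EnsembleConfig",
    "ConfusionCounts",
    "FrequencyMap",
    "SuitabilityMap",
    "sample_pseudo_absences",
    "split_calibration",
    "roc_threshold",
    "tss",
    "confusion",
    "build_frequency_map",
    "ensemble_suitability",
    "suitability_delta",
    "run_plan",
    "EnsembleSuitabilityModel",
]

DEFAULT_METHODS = ("bioclim", "euclidean", "gower", "mahalanobis", "glm")


@dataclass(frozen=True)
class EnsembleConfig:
    """Protocol parameters; defaults are the reference study conditions."""

    n_replicates: int = 50
    calibration_fraction: float = 0.75
    prevalence: float = 0.5
    methods: tuple[str, ...] = DEFAULT_METHODS
    master_seed: int = 0

    def __post_init__(self):
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")
        if not (0 < self.calibration_fraction < 1):
            raise ValueError("calibration_fraction must lie in (0, 1)")
        if not (0 < self.prevalence < 1):
            raise ValueError("prevalence must lie in (0, 1)")


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fn: int
    fp: int
    tn: int

    def __post_init__(self):
        if min(self.tp, self.fn, self.fp, self.tn) < 0:
            raise ValueError("confusion counts must be non-negative")


def confusion(predicted: np.ndarray, truth: np.ndarray) -> ConfusionCounts:
    predicted = np.asarray(predicted, dtype=bool)
    truth = np.asarray(truth, dtype=bool)
    return ConfusionCounts(
        tp=int(np.sum(predicted & truth)),
        fn=int(np.sum(~predicted & truth)),
        fp=int(np.sum(predicted & ~truth)),
        tn=int(np.sum(~predicted & ~truth)),
    )


def tss(c: ConfusionCounts) -> float:
    """True Skill Statistic = sensitivity + specificity - 1, in [-1, 1]."""
    if c.tp + c.fn == 0 or c.fp + c.tn == 0:
        raise ValueError("TSS undefined: a class is empty")
    sens = c.tp / (c.tp + c.fn)
    spec = c.tn / (c.tn + c.fp)
    return sens + spec - 1.0


def sample_pseudo_absences(
    background_cells: np.ndarray,
    presence_cells: np.ndarray,
    prevalence: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Sample pseudo-absence cells without replacement from the background.

    The count is ``n_presence * (1 - prevalence) / prevalence`` (rounded),
    i.e. one pseudo-absence per presence at prevalence 0.5. The background
    must already exclude presence cells; this is asserted.
    """
    background_cells = np.asarray(background_cells)
    presence_cells = np.asarray(presence_cells)
    if len(presence_cells):
        pres = {tuple(c) for c in presence_cells}
        if any(tuple(c) in pres for c in background_cells):
            raise ValueError("background must exclude presence cells")
    n = int(round(len(presence_cells) * (1 - prevalence) / prevalence))
    if n > len(background_cells):
        raise ValueError(
            f"insufficient background: need {n}, have {len(background_cells)}"
        )
    idx = rng.choice(len(background_cells), size=n, replace=False)
    return background_cells[idx]


def split_calibration(labels: np.ndarray, fraction: float, rng: np.random.Generator):
    """Stratified calibration/evaluation index split.

    Each label class is split separately with the calibration count rounded
    to the nearest integer; returns (calibration_idx, evaluation_idx),
    disjoint and exhaustive.
    """
    if not (0 < fraction < 1):
        raise ValueError("fraction must lie in (0, 1)")
    labels = np.asarray(labels)
    cal, ev = [], []
    for value in np.unique(labels):
        idx = np.flatnonzero(labels == value)
        if len(idx) < 2:
            raise ValueError(f"class {value!r} has < 2 records; cannot split")
        perm = rng.permutation(idx)
        n_cal = int(round(fraction * len(idx)))
        n_cal = min(max(n_cal, 1), len(idx) - 1)  # both sides non-empty
        cal.append(perm[:n_cal])
        ev.append(perm[n_cal:])
    return np.sort(np.concatenate(cal)), np.sort(np.concatenate(ev))


def roc_threshold(scores: np.ndarray, labels: np.ndarray) -> float:
    """Binarization threshold maximizing sensitivity + specificity.

    Candidate thresholds are the midpoints between consecutive distinct
    sorted scores; ties are broken toward the smallest threshold. Predicted
    presence is ``score >= threshold``.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(bool)
    if not (labels.any() and (~labels).any()):
        raise ValueError("both labels must be present")
    if not np.all(np.isfinite(scores)):
        raise ValueError("scores must be finite")
    distinct = np.unique(scores)
    if len(distinct) < 2:
        raise ValueError("degenerate scores: all values identical")
    candidates = 0.5 * (distinct[:-1] + distinct[1:])
    best_t, best_tss = None, -np.inf
    for t in candidates:  # smallest-threshold tie-break via strict improvement
        value = tss(confusion(scores >= t, labels))
        if value > best_tss:
            best_t, best_tss = t, value
    return float(best_t)


@dataclass
class FrequencyMap:
    """Per-cell presence-vote frequency for one (method, scenario) pair."""

    method: str
    climate_model: str
    frequency: np.ndarray  # grid-shaped, in [0, 1], multiples of 1/n_replicates
    n_replicates: int
    mean_tss: float


@dataclass
class SuitabilityMap:
    """TSS-weighted consensus of frequency maps."""

    values: np.ndarray  # grid-shaped, in [0, 1]
    weights: dict[tuple[str, str], float] = field(default_factory=dict)


def build_frequency_map(
    method: str,
    climate_model: str,
    replicate_predictions: list[np.ndarray],
    replicate_tss: list[float],
) -> FrequencyMap:
    """Stack binary replicate maps into a vote-frequency map."""
    if not replicate_predictions:
        raise ValueError("no replicate predictions")
    shape = replicate_predictions[0].shape
    if any(p.shape != shape for p in replicate_predictions):
        raise ValueError("replicate grids are incompatible")
    stack = np.array([p.astype(float) for p in replicate_predictions])
    return FrequencyMap(
        method=method,
        climate_model=climate_model,
        frequency=stack.mean(axis=0),
        n_replicates=len(replicate_predictions),
        mean_tss=float(np.mean(replicate_tss)),
    )


def ensemble_suitability(frequency_maps: list[FrequencyMap]) -> SuitabilityMap:
    """Consensus suitability: frequency maps averaged with weights max(TSS, 0).

    Maps whose mean TSS is not positive receive weight 0 (negative weights
    would push the consensus outside [0, 1]); if every weight is 0 there is
    no skilful model and an error is raised.
    """
    if not frequency_maps:
        raise ValueError("no frequency maps")
    shape = frequency_maps[0].frequency.shape
    if any(m.frequency.shape != shape for m in frequency_maps):
        raise ValueError("frequency maps do not share a grid")
    weights = {(m.method, m.climate_model): max(m.mean_tss, 0.0) for m in frequency_maps}
    total = sum(weights.values())
    if total <= 0:
        raise ValueError("no skilful models: all TSS weights are zero")
    values = np.zeros(shape)
    for m in frequency_maps:
        values += weights[(m.method, m.climate_model)] * m.frequency
    return SuitabilityMap(values=values / total, weights=weights)


def suitability_delta(current: SuitabilityMap, future: SuitabilityMap):
    """Future minus current suitability, with loss/gain fractions.

    Returns ``(delta, summary)`` where summary has the fraction of valid
    cells losing (< 0), unchanged (= 0) and gaining (> 0) suitability.
    """
    if current.values.shape != future.values.shape:
        raise ValueError("suitability maps do not share a grid")
    delta = future.values - current.values
    valid = np.isfinite(delta)
    n = int(valid.sum())
    summary = {
        "fraction_losing": float(np.sum(delta[valid] < 0) / n) if n else np.nan,
        "fraction_unchanged": float(np.sum(delta[valid] == 0) / n) if n else np.nan,
        "fraction_gaining": float(np.sum(delta[valid] > 0) / n) if n else np.nan,
        "n_valid": n,
    }
    return delta, summary


def run_plan(config: EnsembleConfig, climate_models: list[str]) -> list[tuple[int, str, str]]:
    """Enumerate every planned model instance (replicate, method, scenario).

    One instance per fitted replicate per method per climate scenario: the
    run plan for 50 replicates x 12 methods x 4 scenarios enumerates 2,400
    instances, yielding one frequency map per (method, scenario).
    """
    return [
        (r, m, c)
        for r in range(config.n_replicates)
        for m in config.methods
        for c in climate_models
    ]


class EnsembleSuitabilityModel(BaseEstimator):
    """Fit the full ensemble protocol on gridded environments.

    Parameters mirror :class:`EnsembleConfig`. ``fit`` takes the presence
    cells and the current environment, plus optional named future
    environments. Fitted attributes:

    ``frequency_maps_`` : list of FrequencyMap (current scenario + futures)
    ``suitability_current_`` : SuitabilityMap (consensus over methods)
    ``suitability_future_`` : dict scenario name -> SuitabilityMap
    ``tss_table_`` : dict (method, scenario) -> mean evaluation TSS
    ``n_fitted_models_`` : replicates x methods x scenarios bookkeeping count
    """

    def __init__(
        self,
        methods=DEFAULT_METHODS,
        n_replicates: int = 50,
        calibration_fraction: float = 0.75,
        prevalence: float = 0.5,
        random_state: int = 0,
    ):
        self.methods = methods
        self.n_replicates = n_replicates
        self.calibration_fraction = calibration_fraction
        self.prevalence = prevalence
        self.random_state = random_state

    def _config(self) -> EnsembleConfig:
        return EnsembleConfig(
            n_replicates=self.n_replicates,
            calibration_fraction=self.calibration_fraction,
            prevalence=self.prevalence,
            methods=tuple(self.methods),
            master_seed=self.random_state,
        )

    def fit(self, presence_cells, current_env: EnvStack, future_envs: dict[str, EnvStack] | None = None):
        config = self._config()
        future_envs = future_envs or {}
        grid = current_env.grid
        presence_cells = np.asarray(presence_cells)
        if len(presence_cells) < 4:
            raise ValueError("too few presence cells for the split protocol")

        valid = current_env.valid_mask()
        valid_cells = np.argwhere(valid)
        pres_set = {tuple(c) for c in presence_cells}
        background = np.array([c for c in valid_cells if tuple(c) not in pres_set])

        # score matrix rows follow valid_cells order; projected per scenario
        env_matrices = {"current": current_env.as_matrix(valid_cells)}
        for name, env in future_envs.items():
            if env.grid != grid:
                raise ValueError(f"future scenario {name!r} grid differs from current")
            env_matrices[name] = env.as_matrix(valid_cells)
        scenarios = list(env_matrices)

        ss = np.random.SeedSequence(self.random_state)
        replicate_seeds = ss.spawn(config.n_replicates)

        votes = {(m, s): [] for m in config.methods for s in scenarios}
        skills = {m: [] for m in config.methods}
        n_fitted = 0
        for rep_ss in replicate_seeds:
            rng = np.random.default_rng(rep_ss)
            pa_cells = sample_pseudo_absences(background, presence_cells, config.prevalence, rng)
            cells = np.vstack([presence_cells, pa_cells])
            labels = np.concatenate([np.ones(len(presence_cells)), np.zeros(len(pa_cells))])
            X = current_env.as_matrix(cells)
            cal_idx, ev_idx = split_calibration(labels, config.calibration_fraction, rng)
            for method in config.methods:
                model = make_model(method)
                if method in PRESENCE_ABSENCE_MODELS:
                    model.fit(X[cal_idx], labels[cal_idx])
                else:
                    model.fit(X[cal_idx][labels[cal_idx] == 1])
                ev_scores = model.score_samples(X[ev_idx])
                threshold = roc_threshold(ev_scores, labels[ev_idx])
                skill = tss(confusion(ev_scores >= threshold, labels[ev_idx] == 1))
                skills[method].append(skill)
                for scen in scenarios:
                    binary = np.full(grid.shape, np.nan)
                    pred = model.score_samples(env_matrices[scen]) >= threshold
                    binary[valid_cells[:, 0], valid_cells[:, 1]] = pred
                    votes[(method, scen)].append(binary)
                    n_fitted += 1

        self.frequency_maps_ = [
            build_frequency_map(m, s, votes[(m, s)], skills[m])
            for m in config.methods
            for s in scenarios
        ]
        self.tss_table_ = {
            (fm.method, fm.climate_model): fm.mean_tss for fm in self.frequency_maps_
        }
        current_maps = [fm for fm in self.frequency_maps_ if fm.climate_model == "current"]
        self.suitability_current_ = ensemble_suitability(current_maps)
        self.suitability_future_ = {}
        for name in future_envs:
            maps = [fm for fm in self.frequency_maps_ if fm.climate_model == name]
            self.suitability_future_[name] = ensemble_suitability(maps)
        self.n_fitted_models_ = n_fitted
        self.valid_mask_ = valid
        return self
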