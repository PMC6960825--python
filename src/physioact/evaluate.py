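"""Leave-one-subject-out evaluation of the full design pipeline.

For every fold one subject is held out; imputation means, normalization
statistics, GA feature selection, hyperparameter choice and classifier
training all use the remaining subjects only, and the held-out subject
provides the test error.  The whole process can be repeated with distinct
seeds, and configurations are compared with a single-tail paired t-test
over the (fold, repetition) error estimates.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as spstats

from .classifiers import default_grid, make_classifier, select_hyperparameters
from .features import FeatureMatrix, build_feature_matrix
from .gaselect import GAConfig, evolve, tournament
from .registry import FeatureRegistry


@dataclass
class PipelineConfig:
    """Configuration of one design pipeline (a cell of the experiment grid)."""

    classifier: str = "lslc"
    nmax: int = 40
    use_ga: bool = True
    ga_generations: int = 30
    ga_branches: int = 1
    ga_population: int = 100
    ga_parents: int = 10
    hyper_grid: list[dict] | None = None
    signals: tuple[str, ...] | None = None
    window_length: float | None = None

    def describe(self) -> dict:
        return {"classifier": self.classifier, "nmax": self.nmax,
                "signals": self.signals, "window_length": self.window_length}


@dataclass
class CVResult:
    """Per-(fold, repetition) errors plus pooled confusion counts."""

    config: dict
    classes: np.ndarray
    subjects: np.ndarray
    errors: np.ndarray                  # shape (n_repetitions, n_folds)
    confusion: np.ndarray               # pooled counts, rows = true class
    selected: list = field(default_factory=list)   # [rep][fold] -> tuple
    fold_stats: dict = field(default_factory=dict)  # subject -> design stats

    @property
    def mean_error(self) -> float:
        total = self.confusion.sum()
        return float(1.0 - np.trace(self.confusion) / total) if total else np.nan

    @property
    def fold_errors(self) -> np.ndarray:
        """Flattened (repetition, fold) error vector, the pairing unit for
        significance tests."""
        return self.errors.ravel()

    def per_class_error(self) -> dict[str, float]:
        """1 - recall per class, from the pooled confusion matrix."""
        out = {}
        for i, c in enumerate(self.classes):
            row = self.confusion[i].sum()
            out[str(c)] = float(1.0 - self.confusion[i, i] / row) if row else np.nan
        return out

    def selection_frequency(self, n_features: int) -> np.ndarray:
        """Fraction of (repetition, fold) runs in which each feature index
        appears in the final chromosome."""
        counts = np.zeros(n_features)
        runs = 0
        for rep in self.selected:
            for feats in rep:
                counts[list(feats)] += 1
                runs += 1
        return counts / runs if runs else counts


def design_statistics(X: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Imputation column means, z-score means and SDs from design rows only.
    All-NaN columns impute to 0; zero-SD columns get SD 1."""
    import warnings
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN columns
        col_means = np.nanmean(np.where(np.isfinite(X), X, np.nan), axis=0)
    col_means = np.where(np.isfinite(col_means), col_means, 0.0)
    Xi = np.where(np.isfinite(X), X, col_means[None, :])
    mu = Xi.mean(axis=0)
    sd = Xi.std(axis=0)
    sd = np.where(sd > 0, sd, 1.0)
    return col_means, mu, sd


def _apply_stats(X, col_means, mu, sd):
    Xi = np.where(np.isfinite(X), X, col_means[None, :])
    return (Xi - mu) / sd


def loso_cv(fm: FeatureMatrix, config: PipelineConfig,
            n_repetitions: int = 1, seed: int = 0) -> CVResult:
    """Leave-one-subject-out cross-validation of the full design pipeline.

    Every design-side quantity (imputation means, normalization statistics,
    GA fitness, hyperparameters) is computed from the k-1 design subjects;
    the held-out subject is only ever scored.
    """
    subjects = np.unique(fm.subjects)
    if len(subjects) < 2:
        raise ValueError("need at least 2 subjects for LOSO CV")
    classes = np.unique(fm.labels)
    n_feat = fm.X.shape[1]
    errors = np.zeros((n_repetitions, len(subjects)))
    confusion = np.zeros((len(classes), len(classes)), dtype=int)
    cls_index = {c: i for i, c in enumerate(classes)}
    selected: list[list[tuple[int, ...]]] = []
    fold_stats: dict[str, dict] = {}

    root = np.random.default_rng(seed)
    rep_seeds = root.integers(0, 2 ** 31 - 1, size=(n_repetitions, len(subjects)))

    for r in range(n_repetitions):
        rep_selected = []
        for i, subj in enumerate(subjects):
            test_mask = fm.subjects == subj
            Xd, yd = fm.X[~test_mask], fm.labels[~test_mask]
            gd = fm.subjects[~test_mask]
            col_means, mu, sd = design_statistics(Xd)
            if r == 0:
                fold_stats[str(subj)] = {"col_means": col_means.copy(),
                                         "mu": mu.copy(), "sd": sd.copy()}
            Zd = _apply_stats(Xd, col_means, mu, sd)
            fold_seed = int(rep_seeds[r, i])

            if config.use_ga:
                ga_cfg = GAConfig(nmax=min(config.nmax, n_feat),
                                  population_size=config.ga_population,
                                  n_parents=config.ga_parents,
                                  generations=config.ga_generations,
                                  branches=config.ga_branches,
                                  seed=fold_seed)
                if config.ga_branches >= 2:
                    chrom = tournament(Zd, yd, ga_cfg)
                else:
                    chrom = evolve(Zd, yd, ga_cfg)
                sel = np.asarray(chrom.features, dtype=int)
            else:
                sel = np.arange(n_feat)
            rep_selected.append(tuple(int(j) for j in sel))

            Zds = Zd[:, sel]
            grid = config.hyper_grid
            if grid is None:
                grid = default_grid(config.classifier, Zds)
            params = grid[0] if len(grid) == 1 else select_hyperparameters(
                config.classifier, Zds, yd, gd, grid, seed=fold_seed)
            model = make_classifier(config.classifier, seed=fold_seed, **params)
            model.fit(Zds, yd)

            Zt = _apply_stats(fm.X[test_mask], col_means, mu, sd)[:, sel]
            yt = fm.labels[test_mask]
            pred = model.predict(Zt)
            errors[r, i] = float(np.mean(pred != yt))
            for t, p in zip(yt, pred):
                confusion[cls_index[t], cls_index[p]] += 1
        selected.append(rep_selected)

    return CVResult(config=config.describe(), classes=classes,
                    subjects=subjects, errors=errors, confusion=confusion,
                    selected=selected, fold_stats=fold_stats)


def paired_significance(errors_a: np.ndarray, errors_b: np.ndarray) -> float:
    """One-sided paired t-test p-value for "b is worse than a"
    (H1: mean(b - a) > 0).  Identical vectors give p = 0.5; a zero-variance
    nonzero shift gives 0 or 1 depending on its sign."""
    a = np.asarray(errors_a, dtype=float)
    b = np.asarray(errors_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired vectors must have equal length")
    d = b - a
    n = len(d)
    mean = d.mean()
    sd = d.std(ddof=1) if n > 1 else 0.0
    if sd == 0.0:
        return 0.5 if mean == 0.0 else (0.0 if mean > 0 else 1.0)
    t = mean / (sd / np.sqrt(n))
    return float(spstats.t.sf(t, n - 1))


def subset_features(fm: FeatureMatrix, registry: FeatureRegistry,
                    signals: tuple[str, ...]) -> FeatureMatrix:
    """Column subset of a full-registry feature matrix for a signal combo."""
    idx = [i for i, e in enumerate(registry.entries) if e.signal in signals]
    sub_registry = FeatureRegistry(tuple(s for s in registry.signals
                                         if s in signals))
    return FeatureMatrix(fm.X[:, idx], [fm.columns[i] for i in idx],
                         fm.labels, fm.subjects, fm.decision_times,
                         sub_registry.hash)


def run_experiment_grid(sessions, signal_combos, window_lengths, classifiers,
                        nmax_grid, n_repetitions: int = 1, seed: int = 0,
                        pipeline_defaults: PipelineConfig | None = None
                        ) -> pd.DataFrame:
    """Evaluate every (signal combo, window length, classifier, Nmax) cell
    with LOSO CV and return a tidy results table.

    Each row carries the cell's mean error, decision count and the flat
    (fold, repetition) error vector; ``p_vs_best`` compares the cell against
    the best cell sharing its signal combo and classifier, with the paired
    one-sided t-test.  A failing cell is marked and the run continues.
    """
    base = pipeline_defaults or PipelineConfig()
    registry = FeatureRegistry()
    rows = []
    for w in window_lengths:
        full_fm = build_feature_matrix(sessions, registry, w)
        for combo in signal_combos:
            fm = subset_features(full_fm, registry, tuple(combo))
            for clf in classifiers:
                for nmax in nmax_grid:
                    cfg = PipelineConfig(
                        classifier=clf, nmax=nmax, use_ga=base.use_ga,
                        ga_generations=base.ga_generations,
                        ga_branches=base.ga_branches,
                        ga_population=base.ga_population,
                        ga_parents=base.ga_parents,
                        hyper_grid=base.hyper_grid,
                        signals=tuple(combo), window_length=w)
                    try:
                        res = loso_cv(fm, cfg, n_repetitions, seed)
                        rows.append({
                            "signals": "+".join(combo), "window": w,
                            "classifier": clf, "nmax": nmax,
                            "error": res.mean_error,
                            "n_decisions": int(res.confusion.sum()),
                            "fold_errors": res.fold_errors,
                            "status": "ok"})
                    except Exception as exc:  # cell failure: mark, continue
                        rows.append({
                            "signals": "+".join(combo), "window": w,
                            "classifier": clf, "nmax": nmax,
                            "error": np.nan, "n_decisions": 0,
                            "fold_errors": None,
                            "status": f"failed: {exc}"})
    df = pd.DataFrame(rows)
    df["p_vs_best"] = np.nan
    for (_, _), grp in df.groupby(["signals", "classifier"]):
        ok = grp[grp["status"] == "ok"]
        if ok.empty:
            continue
        best_idx = ok["error"].idxmin()
        best_err = df.loc[best_idx, "fold_errors"]
        for idx in ok.index:
            if idx == best_idx:
                continue
            df.loc[idx, "p_vs_best"] = paired_significance(
                best_err, df.loc[idx, "fold_errors"])
    return df


def report_window_table(df: pd.DataFrame) -> str:
    """Plain-text report: per signal combo, the best-Nmax error for each
    window length, with the p-value against the best window."""
    lines = []
    windows = sorted(df["window"].unique())
    header = f"{'Signals':<20}{'Par.':<10}" + "".join(
        f"{f'{int(w)} s':>12}" for w in windows)
    lines.append(header)
    lines.append("-" * len(header))
    for combo, grp in df.groupby("signals", sort=False):
        cells = {}
        for w in windows:
            sub = grp[(grp["window"] == w) & (grp["status"] == "ok")]
            if sub.empty:
                cells[w] = None
                continue
            cells[w] = sub.loc[sub["error"].idxmin()]
        valid = {w: c for w, c in cells.items() if c is not None}
        best_w = min(valid, key=lambda w: valid[w]["error"]) if valid else None
        for par in ("error", "nmax", "p"):
            vals = []
            for w in windows:
                c = cells[w]
                if c is None:
                    vals.append(f"{'fail':>12}")
                elif par == "error":
                    vals.append(f"{100 * c['error']:>11.1f}%")
                elif par == "nmax":
                    vals.append(f"{int(c['nmax']):>12d}")
                else:
                    if w == best_w:
                        vals.append(f"{'Best':>12}")
                    else:
                        p = paired_significance(valid[best_w]["fold_errors"],
                                                c["fold_errors"])
                        vals.append(f"{'<0.001':>12}" if p < 0.001
                                    else f"{p:>12.3f}")
            label = {"error": "Error(%)", "nmax": "Nmax", "p": "p-value"}[par]
            lines.append(f"{combo if par == 'error' else '':<20}"
                         f"{label:<10}" + "".join(vals))
    return "\n".join(lines)
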