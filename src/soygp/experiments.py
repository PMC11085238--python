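"""Prediction experiments: k-fold CV, across-population prediction, sweeps.

Prediction ability (PA) is the Pearson correlation between observed values
(here: BLUEs across environments) and GEBVs.  Within-population prediction
uses seeded 10-fold cross-validation with PA averaged over folds;
across-population prediction fits once on the union of training panels and
scores the whole test panel.  Two optimization sweeps mirror the study's
training-set designs — nested panel combinations ordered by genetic
distance, and distance-ranked training-set sizes — and a marker-count
sweep refits on repeated random SNP subsets.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .geno import GenotypeMatrix, allele_frequencies
from .structure import DistanceMatrix, rank_by_distance
from .wgr import GRM, McmcConfig, compute_grm, fit_model

logger = logging.getLogger("soygp")

DEFAULT_TP_SIZES = tuple(range(400, 4001, 400))
DEFAULT_MARKER_SIZES = (100, 300, 500, 1000, 3000, 5000, 10_000, 20_000, 30_000)


@dataclass
class ExperimentConfig:
    """Shared experiment settings (folds, sweep grids, repeats, seed)."""

    model: str = "GBLUP"
    k: int = 10
    tp_sizes: tuple = DEFAULT_TP_SIZES
    marker_set_sizes: tuple = DEFAULT_MARKER_SIZES
    n_repeats: int = 100
    seed: int = 0
    mcmc: McmcConfig | None = None

    def __post_init__(self) -> None:
        if self.k < 2:
            raise ValueError("k must be >= 2")
        if any(s <= 0 for s in self.tp_sizes):
            raise ValueError("tp_sizes must be positive")


@dataclass
class PredictionResult:
    """One experiment's PA with its per-fold/per-repeat replicates."""

    experiment: str
    model: str
    train_label: str
    test_label: str
    pa: float
    replicates: list = field(default_factory=list)
    se: float = float("nan")
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.replicates and not np.isnan(self.pa):
            assert abs(self.pa - float(np.mean(self.replicates))) < 1e-9


def prediction_ability(observed: pd.Series, gebv: pd.Series) -> float:
    """Pearson r between observed phenotypes and GEBVs, aligned by id.

    Pairs with missing observed values are dropped (logged).
    """
    joined = pd.concat([observed.rename("obs"), gebv.rename("pred")],
                       axis=1, join="inner")
    dropped = int(joined["obs"].isna().sum())
    if dropped:
        logger.info("prediction_ability: dropped %d missing observations", dropped)
    joined = joined.dropna()
    if len(joined) < 3:
        raise ValueError("need >= 3 aligned pairs")
    if joined["obs"].std() == 0 or joined["pred"].std() == 0:
        raise ValueError("zero variance in observed or predicted values")
    return float(stats.pearsonr(joined["obs"], joined["pred"])[0])


def make_folds(sample_ids, k: int, seed: int) -> list:
    """Seeded partition into k near-equal disjoint folds.

    A seeded permutation of the ids is split into contiguous blocks whose
    sizes differ by at most one — documented so other implementations can
    reproduce the assignment exactly.
    """
    ids = np.asarray(sample_ids, dtype=object)
    if len(ids) < k:
        raise ValueError("panel smaller than number of folds")
    perm = np.random.default_rng(seed).permutation(len(ids))
    return [list(ids[chunk]) for chunk in np.array_split(perm, k)]


def _fit_predict(g, y_train, test_ids, config, grm=None):
    fit = fit_model(
        config.model, g, y_train, mcmc=config.mcmc, grm=grm,
    )
    return fit.gebv.loc[test_ids]


def kfold_cv(
    g: GenotypeMatrix,
    y: pd.Series,
    config: ExperimentConfig,
    label: str = "panel",
) -> PredictionResult:
    """Within-population k-fold cross-validation, PA averaged over folds."""
    y = y.dropna()
    folds = make_folds(y.index, config.k, config.seed)
    grm = compute_grm(g) if config.model == "GBLUP" else None
    pas = []
    for fold in folds:
        if len(fold) < 3:
            raise ValueError("fold with fewer than 3 samples")
        train = y.drop(index=fold)
        gebv = _fit_predict(g, train, fold, config, grm=grm)
        pas.append(prediction_ability(y.loc[fold], gebv))
    return PredictionResult(
        experiment="kfold_cv",
        model=config.model,
        train_label=label,
        test_label=label,
        pa=float(np.mean(pas)),
        replicates=pas,
        se=float(np.std(pas, ddof=1) / np.sqrt(len(pas))),
        meta={"k": config.k, "seed": config.seed, "n": int(len(y))},
    )


def across_population(
    g: GenotypeMatrix,
    y_train: pd.Series,
    y_test: pd.Series,
    config: ExperimentConfig,
    train_label: str = "train",
    test_label: str = "test",
) -> PredictionResult:
    """Fit once on the training panel(s), score the whole test panel."""
    overlap = set(y_train.index) & set(y_test.index)
    if overlap:
        raise ValueError(f"train/test overlap: {sorted(overlap)[:5]}")
    gebv = _fit_predict(g, y_train.dropna(), list(y_test.index), config)
    pa = prediction_ability(y_test, gebv)
    return PredictionResult(
        experiment="across_population",
        model=config.model,
        train_label=train_label,
        test_label=test_label,
        pa=pa,
        meta={"n_train": int(y_train.notna().sum()), "n_test": int(len(y_test)),
              "seed": config.seed},
    )


def tp_composition_sweep(
    g: GenotypeMatrix,
    blues: pd.Series,
    panels: pd.Series,
    ordered_panels: list,
    test_panel: str,
    config: ExperimentConfig,
) -> list:
    """Nested panel combinations plus singletons as training sets.

    ``ordered_panels`` is the candidate panel order (closest first, e.g.
    from group_distance).  Evaluates the nested prefixes (closest, closest
    two, ..., all) and each panel singly, predicting the test panel — the
    composition design behind combined-training-set reports.
    """
    if len(ordered_panels) < 1:
        raise ValueError("need at least one candidate panel")
    test_ids = panels.index[panels == test_panel]
    y_test = blues.loc[blues.index.intersection(test_ids)]
    combos = [ordered_panels[: i + 1] for i in range(len(ordered_panels))]
    combos += [[p] for p in ordered_panels[1:]]  # singletons beyond the first
    results = []
    for combo in combos:
        train_ids = panels.index[panels.isin(combo)]
        y_train = blues.loc[blues.index.intersection(train_ids)]
        res = across_population(
            g, y_train, y_test, config,
            train_label="".join(map(str, combo)), test_label=test_panel,
        )
        res.experiment = "tp_composition_sweep"
        results.append(res)
    return results


def tp_size_sweep(
    g: GenotypeMatrix,
    blues: pd.Series,
    ranked_candidates: list,
    y_test: pd.Series,
    config: ExperimentConfig,
) -> list:
    """Training sets of increasing size taken as prefixes of a distance ranking.

    ``ranked_candidates`` must already be ordered closest-first (see
    structure.rank_by_distance); size s trains on the first s candidates.
    """
    sizes = [s for s in config.tp_sizes if s <= len(ranked_candidates)]
    if not sizes:
        raise ValueError("no tp_size fits the candidate pool")
    if max(config.tp_sizes) > len(ranked_candidates):
        logger.warning(
            "tp sizes above pool size %d skipped", len(ranked_candidates)
        )
    results = []
    for s in sizes:
        y_train = blues.loc[blues.index.intersection(ranked_candidates[:s])]
        res = across_population(
            g, y_train, y_test, config,
            train_label=f"closest-{s}", test_label="BP",
        )
        res.experiment = "tp_size_sweep"
        res.meta["tp_size"] = s
        results.append(res)
    return results


def marker_subset_sweep(
    g: GenotypeMatrix,
    y_train: pd.Series,
    y_test: pd.Series,
    config: ExperimentConfig,
) -> list:
    """PA versus marker count: repeated uniform random SNP subsets.

    For each size, ``n_repeats`` subsets are drawn without replacement
    (seeded) and the model is refitted per subset; the full marker set is
    evaluated once (SE = 0).  Returns one PredictionResult per size with
    mean ± SE over repeats.
    """
    m = g.n_markers
    sizes = [s for s in config.marker_set_sizes if s <= m]
    rng = np.random.default_rng(config.seed)
    results = []
    for s in sizes + [m]:
        n_rep = 1 if s == m else config.n_repeats
        pas = []
        for _ in range(n_rep):
            if s == m:
                gsub = g
            else:
                cols = np.sort(rng.choice(m, size=s, replace=False))
                gsub = g.subset(markers=list(g.marker_ids[cols]))
            res = across_population(gsub, y_train, y_test, config)
            pas.append(res.pa)
        results.append(
            PredictionResult(
                experiment="marker_subset_sweep",
                model=config.model,
                train_label="train",
                test_label="test",
                pa=float(np.mean(pas)),
                replicates=pas,
                se=float(np.std(pas, ddof=1) / np.sqrt(len(pas)))
                if len(pas) > 1 else 0.0,
                meta={"n_markers": int(s), "n_repeats": n_rep,
                      "seed": config.seed},
            )
        )
    return results


def results_to_frame(results: list) -> pd.DataFrame:
    """Tidy table: one row per result, replicates joined as a string."""
    rows = []
    for r in results:
        row = {
            "experiment": r.experiment, "model": r.model,
            "train": r.train_label, "test": r.test_label,
            "pa": r.pa, "se": r.se,
            "n_replicates": len(r.replicates),
        }
        row.update({k: v for k, v in r.meta.items() if np.isscalar(v)})
        rows.append(row)
    return pd.DataFrame(rows)
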