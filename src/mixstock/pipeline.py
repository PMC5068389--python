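"""End-to-end resampling experiments and single-dataset fits.

``run_scenario`` executes one simulation cell: R independent resampling
runs, each drawing a nursery-source dataset (25 fish per sampled source)
and a mixed-stock dataset (100 unlabeled fish at permuted proportions
{0.1, 0.2, 0.3, 0.4}), fitting the unconditional mixture at the true K
for the proportion/signature metrics and, optionally, running BIC model
selection over K = max(1, K_S)..8 for the K metrics.

``run_experiment`` drives a whole scenario grid from an
:class:`ExperimentConfig` and writes the long-format summary CSV.
``fit_single`` is the user-data path: standardize, fit, select.

Seed discipline: every scenario carries its own seed; per-run child
seeds are spawned from it with ``numpy`` SeedSequences keyed by the run
index, so results are bit-identical regardless of worker count.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .baseline import ObservationTable, read_observations, standardize
from .em import EMControls, MixtureFit, em_fit, initialize
from .evaluate import (EvaluationSummary, RunRecord, match_components,
                       summaries_to_frame, summarize_scenario)
from .selection import K_MAX_DEFAULT, SelectionResult, estimate_k
from .simulate import (DEFAULT_PROPORTIONS, DEFAULT_SPREAD, ScenarioConfig,
                       build_scenario_grid, draw_mixed_dataset,
                       draw_nursery_dataset, random_baseline,
                       sample_known_sources)

__all__ = ["ExperimentConfig", "run_scenario", "run_experiment", "fit_single"]

logger = logging.getLogger(__name__)


def _run_one(scenario: ScenarioConfig, run_seed: np.random.SeedSequence,
             controls: EMControls, select_k: bool, K_max: int,
             criterion: str) -> RunRecord:
    """One resampling run of a scenario (draw -> init -> EM -> selection)."""
    cohort = scenario.cohort
    s_pick, s_nursery, s_mixed, s_fit = run_seed.spawn(4)
    sampled = (sample_known_sources(cohort, scenario.K_S, seed=s_pick)
               if scenario.K_S else ())
    labeled = draw_nursery_dataset(cohort, sampled,
                                   scenario.n_nursery_per_source,
                                   seed=s_nursery)
    mixed, truth = draw_mixed_dataset(cohort, scenario.proportions,
                                      scenario.n_mixed, seed=s_mixed)
    truth = replace(truth, sampled_sources=tuple(sampled))
    ctl = replace(controls,
                  seed=int(s_fit.generate_state(1)[0] % (2**31)))
    # proportion / signature metrics use the true K
    init = initialize(labeled if labeled.n else None, mixed, cohort.K, ctl)
    fit = em_fit(labeled if labeled.n else None, mixed, cohort.K,
                 init=init, controls=ctl)
    matching = match_components(fit.mu_hat, fit.provenance, truth.true_mus)
    record = RunRecord(truth=truth, fit=fit, matching=matching)
    if select_k:
        sel = estimate_k(labeled if labeled.n else None, mixed,
                         K_S=len(sampled), K_max=K_max, controls=ctl,
                         criterion=criterion)
        record.K_hat = sel.K_hat
        record.delta_bic = sel.delta_bic
    return record


def run_scenario(
    scenario: ScenarioConfig,
    controls: EMControls = EMControls(),
    select_k: bool = False,
    K_max: int = K_MAX_DEFAULT,
    criterion: str = "BIC",
    n_workers: int = 1,
    return_records: bool = False,
) -> EvaluationSummary | tuple[EvaluationSummary, list[RunRecord]]:
    """Run all R resampling runs of one scenario and summarize them.

    Runs whose fit raises are dropped and counted; metrics use the
    successful runs only.
    """
    seeds = np.random.SeedSequence(scenario.seed).spawn(scenario.R)

    def one(r: int) -> RunRecord | Exception:
        try:
            return _run_one(scenario, seeds[r], controls, select_k,
                            K_max, criterion)
        except Exception as exc:  # noqa: BLE001 - per-run isolation
            return exc

    if n_workers > 1:
        from joblib import Parallel, delayed
        results = Parallel(n_jobs=n_workers)(
            delayed(one)(r) for r in range(scenario.R))
    else:
        results = [one(r) for r in range(scenario.R)]
    records = [r for r in results if isinstance(r, RunRecord)]
    n_failed = scenario.R - len(records)
    if n_failed:
        logger.warning("scenario %s: %d/%d runs failed",
                       scenario.label, n_failed, scenario.R)
    summary = summarize_scenario(records, K_true=scenario.cohort.K,
                                 n_failed=n_failed, scenario=scenario.label,
                                 K_S=scenario.K_S,
                                 separation=scenario.separation)
    return (summary, records) if return_records else summary


@dataclass
class ExperimentConfig:
    """Declarative description of a simulation experiment.

    Virtual mode builds a random K-source baseline and rescales it to
    each requested separation; observed mode reads signature-set CSVs.
    A serialized copy of the config is written next to the outputs.
    """

    K: int = 4
    J: int = 7
    spread: float = DEFAULT_SPREAD
    separations: tuple[float, ...] = (0.5, 1.5, 2.5, 3.5, 4.5, 5.5)
    K_S_values: tuple[int, ...] = (0, 1, 2, 3, 4)
    n_nursery_per_source: int = 25
    n_mixed: int = 100
    proportions: tuple[float, ...] = DEFAULT_PROPORTIONS
    R: int = 1000
    base_seed: int = 0
    select_k: bool = False
    K_max: int = K_MAX_DEFAULT
    criterion: str = "BIC"
    controls: EMControls = field(default_factory=EMControls)
    signature_files: tuple[tuple[str, str], ...] = ()  # (means, covs) pairs
    output_dir: str = "mixstock-out"
    n_workers: int = 1

    @staticmethod
    def from_yaml(path: str | Path) -> "ExperimentConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        ctl = EMControls(**raw.pop("controls", {}))
        known = {f.name for f in dataclasses.fields(ExperimentConfig)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("separations", "K_S_values", "proportions"):
            if key in raw and raw[key] is not None:
                raw[key] = tuple(raw[key])
        if "signature_files" in raw:
            raw["signature_files"] = tuple(tuple(pair)
                                           for pair in raw["signature_files"])
        return ExperimentConfig(controls=ctl, **raw)

    def to_yaml(self, path: str | Path) -> None:
        d = dataclasses.asdict(self)
        d["controls"] = dataclasses.asdict(self.controls)
        Path(path).write_text(yaml.safe_dump(d, sort_keys=False))

    def cohorts(self):
        from .baseline import read_signature_set
        if self.signature_files:
            return [read_signature_set(m, c) for m, c in self.signature_files]
        base = random_baseline(self.K, self.J, target_sep=2.5,
                               spread=self.spread,
                               seed=np.random.SeedSequence(self.base_seed,
                                                           spawn_key=(0xB,)))
        return [base]

    def scenarios(self) -> list[ScenarioConfig]:
        seps = None if self.signature_files else self.separations
        return build_scenario_grid(
            self.cohorts(), self.K_S_values, separations=seps,
            n_nursery_per_source=self.n_nursery_per_source,
            n_mixed=self.n_mixed, proportions=self.proportions,
            R=self.R, base_seed=self.base_seed)


def run_experiment(config: ExperimentConfig) -> pd.DataFrame:
    """Run the whole scenario grid and write summary tables.

    Writes ``summary.csv`` (long format: scenario, K_S, separation,
    metric, value, R_effective) and a provenance copy of the config into
    ``config.output_dir``; returns the summary frame.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    config.to_yaml(out / "config.yaml")
    scenarios = config.scenarios()
    if not scenarios:
        raise ValueError("configuration produced no scenarios")
    summaries = []
    for i, sc in enumerate(scenarios):
        logger.info("scenario %d/%d: %s", i + 1, len(scenarios), sc.label)
        summaries.append(run_scenario(
            sc, controls=config.controls, select_k=config.select_k,
            K_max=config.K_max, criterion=config.criterion,
            n_workers=config.n_workers))
    frame = summaries_to_frame(summaries)
    frame.to_csv(out / "summary.csv", index=False)
    return frame


def fit_single(
    nursery: ObservationTable | str | Path | None,
    mixed: ObservationTable | str | Path,
    K: int | str = "auto",
    controls: EMControls = EMControls(),
    K_max: int = K_MAX_DEFAULT,
    criterion: str = "BIC",
    output_dir: str | Path | None = None,
) -> tuple[MixtureFit, SelectionResult | None]:
    """Fit user-supplied data: standardize, initialize, EM, optionally select K.

    Both tables are z-scored with pooled (nursery + mixed) per-variable
    statistics so the two datasets share one scale; the transform
    parameters are written alongside the fit when ``output_dir`` is set.
    """
    if isinstance(mixed, (str, Path)):
        mixed = read_observations(mixed)
    if isinstance(nursery, (str, Path)):
        nursery = read_observations(nursery)
    if mixed.n == 0:
        raise ValueError("mixed-stock table is empty")
    if nursery is not None and tuple(nursery.panel.names) != tuple(mixed.panel.names):
        raise ValueError(
            "nursery and mixed tables disagree on ratio columns: "
            f"{list(nursery.panel.names)} vs {list(mixed.panel.names)}")
    pooled = (pd.concat([nursery.data, mixed.data], ignore_index=True)
              if nursery is not None and nursery.n else mixed.data)
    pooled_table = ObservationTable(pooled, mixed.panel)
    _, params = standardize(pooled_table)
    mixed_std, _ = standardize(mixed, params)
    nursery_std = None
    if nursery is not None and nursery.n:
        nursery_std, _ = standardize(nursery, params)
    K_S = 0 if nursery_std is None else \
        nursery_std.data["source"].nunique()
    selection: SelectionResult | None = None
    if K == "auto":
        selection = estimate_k(nursery_std, mixed_std, K_S=K_S, K_max=K_max,
                               controls=controls, criterion=criterion)
        fit = selection.fits[selection.K_hat]
    else:
        init = initialize(nursery_std, mixed_std, int(K), controls)
        fit = em_fit(nursery_std, mixed_std, int(K), init=init,
                     controls=controls)
    if output_dir is not None:
        out = Path(output_dir)
        out.mkdir(parents=True, exist_ok=True)
        fit.to_json(out / "fit.json")
        params.to_csv(out / "standardization.csv")
        if selection is not None:
            selection.to_frame().to_csv(out / "selection.csv", index=False)
    return fit, selection
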