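"""End-to-end pipeline: simulate -> thin -> extract -> select -> fit ->
evaluate -> project -> classify -> change -> report.

Every stage writes its artifacts plus a JSON manifest recording the master
seed and a hash of the configuration, so any output file is traceable to
the exact run that produced it. All randomness derives from the single
master seed; re-running with the same configuration reproduces every CSV
byte for byte.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .evaluate import (
    evaluate_replicates,
    jackknife_gains,
    percent_contribution,
    permutation_importance,
    response_curve,
)
from .grid_io import (
    EnvStack,
    OccurrenceSet,
    RasterGrid,
    read_ascii_grid,
    read_samples_csv,
    write_ascii_grid,
    write_samples_csv,
)
from .mapping import (
    ClassificationScheme,
    ClassifiedMap,
    area_percentages,
    change_summary,
    classify,
    jenks_breaks,
    overlay_code,
)
from .maxent import ReplicateConfig, SuitabilityMap, predict_logistic, run_replicates
from .occurrences import PresenceTable, deduplicate, extract_presence_values, fishnet_thin
from .selection import SelectionRule, greedy_prune, pearson_matrix
from .synthetic import TruthConfig, generate_env_stack, sample_occurrences, true_suitability

__all__ = ["PipelineConfig", "Pipeline", "DependencyError", "STAGES"]

STAGES = ["simulate", "thin", "extract", "select", "fit", "evaluate",
          "project", "classify", "change", "report"]


class DependencyError(RuntimeError):
    """A stage's prerequisite artifact is missing."""


@dataclass
class ScenarioSpec:
    label: str
    driver_offset: float = 0.0


@dataclass
class PipelineConfig:
    out_dir: str = "sdmax_run"
    seed: int = 0
    grid: dict = field(default_factory=lambda: {
        "nrows": 80, "ncols": 80, "xllcorner": 100.0, "yllcorner": 20.0,
        "cellsize": 0.05, "nodata_value": -9999.0,
    })
    truth: TruthConfig = field(default_factory=TruthConfig)
    scenarios: list[ScenarioSpec] = field(default_factory=lambda: [
        ScenarioSpec("current", 0.0),
        ScenarioSpec("2050s", 1.5),
        ScenarioSpec("2070s", 2.5),
    ])
    change_pairs: list[tuple[str, str]] = field(default_factory=lambda: [
        ("current", "2050s"), ("2050s", "2070s"),
    ])
    selection: SelectionRule = field(default_factory=lambda: SelectionRule(
        priority=["bio1", "bio13"], always_keep=[]))
    replicates: ReplicateConfig = field(default_factory=ReplicateConfig)
    scheme: ClassificationScheme = field(default_factory=ClassificationScheme)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        kwargs: dict = {}
        for key in ("out_dir", "seed", "grid"):
            if key in raw:
                kwargs[key] = raw[key]
        if "truth" in raw:
            kwargs["truth"] = TruthConfig(**{
                **raw["truth"],
                "correlated_pairs": [tuple(p) for p in raw["truth"].get(
                    "correlated_pairs", TruthConfig().correlated_pairs)],
            })
        if "scenarios" in raw:
            kwargs["scenarios"] = [ScenarioSpec(**s) for s in raw["scenarios"]]
        if "change_pairs" in raw:
            kwargs["change_pairs"] = [tuple(p) for p in raw["change_pairs"]]
        if "selection" in raw:
            kwargs["selection"] = SelectionRule(**raw["selection"])
        if "replicates" in raw:
            kwargs["replicates"] = ReplicateConfig(**raw["replicates"])
        if "scheme" in raw:
            kwargs["scheme"] = ClassificationScheme(**{
                k: tuple(v) if isinstance(v, list) else v for k, v in raw["scheme"].items()})
        cfg = cls(**kwargs)
        # the master seed governs every stage
        cfg.truth.seed = cfg.seed
        cfg.replicates.seed = cfg.seed + 1
        return cfg

    def config_hash(self) -> str:
        blob = json.dumps(_serializable(asdict(self)), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _serializable(obj):
    if isinstance(obj, dict):
        return {k: _serializable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_serializable(v) for v in obj]
    if isinstance(obj, (np.integer, np.floating)):
        return obj.item()
    return obj


class Pipeline:
    """Stage runner with on-disk artifacts and lazy in-memory state."""

    def __init__(self, config: PipelineConfig):
        self.config = config
        self.out = Path(config.out_dir)
        self._stacks: dict[str, EnvStack] = {}
        self._occurrences: OccurrenceSet | None = None
        self._thinned: OccurrenceSet | None = None
        self._table: PresenceTable | None = None
        self._retained: list[str] | None = None
        self._replicates = None
        self._mean_maps: dict[str, SuitabilityMap] = {}
        self._classified: dict[str, ClassifiedMap] = {}

    # -- manifest ------------------------------------------------------------

    def _manifest(self, stage: str, outputs: list[str], extra: dict | None = None) -> None:
        path = self.out / f"manifest_{stage}.json"
        doc = {
            "stage": stage,
            "seed": self.config.seed,
            "config_hash": self.config.config_hash(),
            "package_version": __version__,
            "outputs": sorted(outputs),
        }
        if extra:
            doc.update(_serializable(extra))
        path.parent.mkdir(parents=True, exist_ok=True)
        path.write_text(json.dumps(doc, indent=1, sort_keys=True) + "\n")

    # -- lazy state ----------------------------------------------------------

    def _stack(self, label: str) -> EnvStack:
        if label not in self._stacks:
            stack_dir = self.out / "stacks" / label
            if not stack_dir.is_dir():
                raise DependencyError(f"stack {label!r} missing; run the 'simulate' stage first")
            layers = [read_ascii_grid(p) for p in sorted(stack_dir.glob("*.asc"))]
            order = {v: i for i, v in enumerate(self.config.truth.variables)}
            layers.sort(key=lambda g: order.get(g.variable_name, 99))
            self._stacks[label] = EnvStack(layers=layers, scenario_label=label)
        return self._stacks[label]

    def _current_label(self) -> str:
        return self.config.scenarios[0].label

    def _get_thinned(self) -> OccurrenceSet:
        if self._thinned is None:
            path = self.out / "occurrences_thinned.csv"
            if not path.exists():
                raise DependencyError("thinned occurrences missing; run the 'thin' stage first")
            self._thinned, _ = read_samples_csv(path)
        return self._thinned

    def _get_table(self) -> PresenceTable:
        if self._table is None:
            path = self.out / "presence_table.csv"
            if not path.exists():
                raise DependencyError("presence table missing; run the 'extract' stage first")
            df = pd.read_csv(path)
            variables = [c for c in df.columns if c not in ("lon", "lat")]
            self._table = PresenceTable(data=df, variables=variables,
                                        n_raw=len(df), n_effective=len(df))
        return self._table

    def _get_retained(self) -> list[str]:
        if self._retained is None:
            path = self.out / "retained_variables.txt"
            if not path.exists():
                raise DependencyError("retained variables missing; run the 'select' stage first")
            self._retained = path.read_text().split()
        return self._retained

    def _get_replicates(self):
        if self._replicates is None:
            # deterministic refit from the same master seed
            stack = self._stack(self._current_label())
            occ = self._get_thinned()
            variables = self._get_retained()
            self._replicates, mean_map = run_replicates(occ, stack, self.config.replicates,
                                                        variables=variables)
            self._mean_maps[self._current_label()] = mean_map
        return self._replicates

    def _get_mean_map(self, label: str) -> SuitabilityMap:
        if label not in self._mean_maps:
            path = self.out / "suitability" / f"{label}.asc"
            if path.exists():
                grid = read_ascii_grid(path, variable_name="suitability")
                self._mean_maps[label] = SuitabilityMap(grid=grid, scenario_label=label)
            elif label == self._current_label():
                self._get_replicates()
            else:
                raise DependencyError(f"suitability map for {label!r} missing; "
                                      "run the 'project' stage first")
        return self._mean_maps[label]

    # -- stages --------------------------------------------------------------

    def run_stage(self, stage: str) -> None:
        if stage not in STAGES:
            raise ValueError(f"unknown stage {stage!r}; stages are {STAGES}")
        getattr(self, f"stage_{stage}")()

    def run_all(self) -> None:
        for stage in STAGES:
            self.run_stage(stage)

    def stage_simulate(self) -> None:
        cfg = self.config
        outputs = []
        header = dict(cfg.grid)
        for scen in cfg.scenarios:
            stack = generate_env_stack(header, cfg.truth, scenario_label=scen.label,
                                       driver_offset=scen.driver_offset)
            self._stacks[scen.label] = stack
            stack_dir = self.out / "stacks" / scen.label
            for layer in stack:
                p = stack_dir / f"{layer.variable_name}.asc"
                write_ascii_grid(layer, p)
                outputs.append(str(p.relative_to(self.out)))
            manifest = stack_dir / "stack.txt"
            manifest.write_text("".join(f"{g.variable_name} {g.units}\n" for g in stack))
        current = self._stacks[self._current_label()]
        truth = true_suitability(current, cfg.truth)
        write_ascii_grid(truth, self.out / "truth_suitability.asc")
        outputs.append("truth_suitability.asc")
        occ = sample_occurrences(truth, cfg.truth)
        self._occurrences = occ
        write_samples_csv(occ, self.out / "occurrences.csv")
        outputs.append("occurrences.csv")
        self._manifest("simulate", outputs)

    def stage_thin(self) -> None:
        path = self.out / "occurrences.csv"
        if self._occurrences is None:
            if not path.exists():
                raise DependencyError("occurrences missing; run the 'simulate' stage first")
            self._occurrences, _ = read_samples_csv(path)
        template = self._stack(self._current_label()).template()
        dedup, rep1 = deduplicate(self._occurrences)
        thinned, rep2 = fishnet_thin(dedup, template)
        self._thinned = thinned
        write_samples_csv(thinned, self.out / "occurrences_thinned.csv")
        self._manifest("thin", ["occurrences_thinned.csv"],
                       {"dedup_report": rep1, "thin_report": rep2})

    def stage_extract(self) -> None:
        stack = self._stack(self._current_label())
        table = extract_presence_values(self._get_thinned(), stack)
        self._table = table
        table.data.to_csv(self.out / "presence_table.csv", index=False)
        self._manifest("extract", ["presence_table.csv"], {
            "n_raw": table.n_raw, "n_effective": table.n_effective,
            "n_dropped_nodata": table.n_dropped_nodata,
            "n_dropped_outside": table.n_dropped_outside,
        })

    def stage_select(self) -> None:
        table = self._get_table()
        corr = pearson_matrix(table)
        retained = greedy_prune(corr, self.config.selection)
        self._retained = retained
        corr.to_frame().to_csv(self.out / "correlation_matrix.csv")
        (self.out / "retained_variables.txt").write_text("\n".join(retained) + "\n")
        self._manifest("select", ["correlation_matrix.csv", "retained_variables.txt"],
                       {"retained": retained})

    def stage_fit(self) -> None:
        replicates = self._get_replicates()
        outputs = []
        model_dir = self.out / "models"
        model_dir.mkdir(parents=True, exist_ok=True)
        for i, res in enumerate(replicates):
            p = model_dir / f"replicate_{i}.lambdas.txt"
            _write_lambdas(res.model, p)
            outputs.append(str(p.relative_to(self.out)))
        label = self._current_label()
        smap_path = self.out / "suitability" / f"{label}.asc"
        write_ascii_grid(self._mean_maps[label].grid, smap_path)
        outputs.append(str(smap_path.relative_to(self.out)))
        self._manifest("fit", outputs, {
            "n_replicates": len(replicates),
            "final_gains": [round(r.model.gain, 6) for r in replicates],
        })

    def stage_evaluate(self) -> None:
        replicates = self._get_replicates()
        summary, per_rep = evaluate_replicates(replicates)
        summary.to_csv(self.out / "metrics_summary.csv")
        rows = [{"replicate": i, "AUC": m.auc, "Kappa": m.kappa, "TSS": m.tss,
                 "threshold": m.threshold_used} for i, m in enumerate(per_rep)]
        pd.DataFrame(rows).to_csv(self.out / "metrics_replicates.csv", index=False)

        pc = pd.concat([percent_contribution(r.model) for r in replicates], axis=1).mean(axis=1)
        pi = pd.concat(
            [permutation_importance(r.model, seed=self.config.seed + 100 + i)
             for i, r in enumerate(replicates)], axis=1).mean(axis=1)
        imp = pd.DataFrame({"percent_contribution": 100 * pc / pc.sum(),
                            "permutation_importance": 100 * pi / pi.sum()})
        imp.index.name = "variable"
        imp.to_csv(self.out / "variable_importance.csv")

        stack = self._stack(self._current_label())
        table = self._get_table()
        variables = self._get_retained()
        jk, gain_all = jackknife_gains(table, stack, variables, self.config.replicates)
        jk.index.name = "variable"
        jk.to_csv(self.out / "jackknife_gains.csv")

        curves = {}
        for v in variables:
            rc = response_curve(table, stack, v, config=self.config.replicates)
            curves[v] = rc
        curve_df = pd.DataFrame({
            f"{v}_{col}": (rc.grid if col == "value" else rc.probability)
            for v, rc in curves.items() for col in ("value", "probability")
        })
        curve_df.to_csv(self.out / "response_curves.csv", index=False)
        self._manifest("evaluate", ["metrics_summary.csv", "metrics_replicates.csv",
                                    "variable_importance.csv", "jackknife_gains.csv",
                                    "response_curves.csv"],
                       {"gain_all": round(gain_all, 6)})

    def stage_project(self) -> None:
        replicates = self._get_replicates()
        outputs = []
        for scen in self.config.scenarios[1:]:
            stack = self._stack(scen.label)
            mask = stack.valid_mask()
            template = stack.template()
            acc = np.zeros_like(template.values)
            for res in replicates:
                # fitted on the current scenario, projected onto this one
                smap = predict_logistic(res.model, stack)
                acc += np.where(mask, smap.grid.values, 0.0)
            mean_vals = np.where(mask, acc / len(replicates), template.nodata_value)
            smap = SuitabilityMap(grid=template.with_values(mean_vals, "mean_suitability"),
                                  model_id="mean", scenario_label=scen.label)
            self._mean_maps[scen.label] = smap
            p = self.out / "suitability" / f"{scen.label}.asc"
            write_ascii_grid(smap.grid, p)
            outputs.append(str(p.relative_to(self.out)))
        self._manifest("project", outputs)

    def stage_classify(self) -> None:
        outputs = []
        areas = []
        for scen in self.config.scenarios:
            smap = self._get_mean_map(scen.label)
            cmap = classify(smap, self.config.scheme)
            self._classified[scen.label] = cmap
            p = self.out / "classified" / f"{scen.label}.asc"
            write_ascii_grid(cmap.grid, p, precision=6)
            outputs.append(str(p.relative_to(self.out)))
            df = area_percentages(cmap)
            df.insert(0, "scenario", scen.label)
            areas.append(df)
        pd.concat(areas, ignore_index=True).to_csv(self.out / "area_percentages.csv", index=False)
        outputs.append("area_percentages.csv")
        # report data-driven Jenks breaks alongside the fixed default scheme
        current = self._get_mean_map(self._current_label())
        vals = current.grid.values[current.grid.valid_mask()]
        jb = jenks_breaks(vals, k=4, seed=self.config.seed)
        self._manifest("classify", outputs, {"jenks_breaks": [round(b, 6) for b in jb],
                                             "scheme_breaks": list(self.config.scheme.breaks)})

    def stage_change(self) -> None:
        if len(self.config.scenarios) < 2 or not self.config.change_pairs:
            raise DependencyError("change stage needs at least two scenarios and a change pair")
        outputs = []
        summaries = []
        for first, second in self.config.change_pairs:
            for label in (first, second):
                if label not in self._classified:
                    smap = self._get_mean_map(label)
                    self._classified[label] = classify(smap, self.config.scheme)
            change = overlay_code(self._classified[first], self._classified[second])
            p = self.out / "change" / f"{first}_to_{second}.asc"
            write_ascii_grid(change.grid, p, precision=6)
            outputs.append(str(p.relative_to(self.out)))
            df = change_summary(change)
            df.insert(0, "pair", f"{first}->{second}")
            summaries.append(df)
        pd.concat(summaries, ignore_index=True).to_csv(self.out / "change_summary.csv", index=False)
        outputs.append("change_summary.csv")
        self._manifest("change", outputs)

    def stage_report(self) -> None:
        wanted = ["metrics_summary.csv", "variable_importance.csv", "jackknife_gains.csv",
                  "area_percentages.csv", "change_summary.csv", "retained_variables.txt"]
        present = [w for w in wanted if (self.out / w).exists()]
        missing = [w for w in wanted if w not in present]
        if missing:
            raise DependencyError(f"report inputs missing: {missing}; run earlier stages first")
        doc = {"artifacts": present, "seed": self.config.seed,
               "config_hash": self.config.config_hash()}
        (self.out / "report.json").write_text(json.dumps(doc, indent=1, sort_keys=True) + "\n")
        self._manifest("report", ["report.json"])


def _write_lambdas(model, path: Path) -> None:
    """Plain-text lambdas file: feature, weight, scaling min/max, footer."""
    lines = []
    for feat, lam, (lo, hi) in zip(model.feature_set.features, model.lambdas,
                                   model.feature_set.scaling):
        lines.append(f"{feat.name}, {lam:.10g}, {lo:.10g}, {hi:.10g}")
    lines.append(f"log_partition, {model.log_partition:.10g}")
    lines.append(f"entropy, {model.entropy:.10g}")
    path.write_text("\n".join(lines) + "\n")
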