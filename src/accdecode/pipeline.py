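"""End-to-end runs: simulate -> preprocess -> decode -> excursions -> encoding stats.

A run is driven by a :class:`RunConfig` (round-trippable through YAML/JSON).
Every stochastic stage carries its own mandatory seed, all outputs are
plain-text CSV/JSON, and a manifest records the config hash, seeds and every
file written, so that re-running the same config reproduces the outputs.
"""

from __future__ import annotations

import hashlib
import json
import sys
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .decoders import crossvalidate, error_map
from .encoding import feeder_classifier_all, informative_cells, excursion_related_cells
from .excursions import (
    detect_excursion_trials, endpoint_concentration_test, align_onsets,
    preference_record,
)
from .nets import TrainConfig
from .preprocessing import build_ensemble
from .session import SessionBundle, read_session, write_session
from .simulate import SimulatorConfig, make_session

__all__ = ["RunConfig", "run_pipeline", "make_report"]

STAGES = ("simulate", "decode", "excursions", "encoding", "report")


class ConfigError(ValueError):
    pass


class StageError(RuntimeError):
    pass


@dataclass
class RunConfig:
    out_dir: str = "run"
    session_dir: str | None = None          # load instead of simulating
    seeds: dict = field(default_factory=dict)  # per-stage seeds, all mandatory
    simulator: dict = field(default_factory=dict)
    stages: tuple[str, ...] = STAGES
    n_sets_decode: int = 10
    n_sets_detect: int = 10
    n_sets_lasso: int = 50
    n_reps_classifier: int = 10
    epochs: int = 100
    detect_method: str = "dann"

    def to_dict(self) -> dict:
        d = asdict(self)
        d["stages"] = list(self.stages)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "stages" in d:
            d["stages"] = tuple(d["stages"])
        return cls(**d)

    def validate(self) -> None:
        needed = {"simulate", "decode", "excursions", "encoding"} & set(self.stages)
        if self.session_dir is not None:
            needed.discard("simulate")
        missing = [s for s in needed if s not in self.seeds]
        if missing:
            raise ConfigError(f"missing seeds for stages: {missing}")


def _log(stage: str, msg: str) -> None:
    print(f"[{stage}] {msg}", file=sys.stderr)


def _write_json(path: Path, obj) -> None:
    def default(o):
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, (np.floating, np.integer)):
            return o.item()
        raise TypeError(type(o))
    path.write_text(json.dumps(obj, indent=1, default=default, allow_nan=True))


def run_pipeline(config: RunConfig) -> dict:
    """Execute the configured stages; returns the manifest."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {
        "version": __version__,
        "config": config.to_dict(),
        "config_hash": hashlib.sha256(
            json.dumps(config.to_dict(), sort_keys=True).encode()
        ).hexdigest(),
        "seeds": dict(config.seeds),
        "outputs": [],
        "stages": [],
        "started": time.strftime("%Y-%m-%dT%H:%M:%S"),
    }

    def record(stage, *paths):
        manifest["stages"].append(stage)
        manifest["outputs"] += [str(p) for p in paths]

    train_config = TrainConfig(epochs=config.epochs)
    session: SessionBundle | None = None
    results: dict = {}
    try:
        if config.session_dir is not None:
            session = read_session(config.session_dir)
            _log("simulate", f"loaded session from {config.session_dir}")
        elif "simulate" in config.stages:
            _log("simulate", "generating session")
            sim = SimulatorConfig.from_dict(config.simulator)
            session = make_session(sim, seed=config.seeds["simulate"])
            sdir = out / "session"
            write_session(session, sdir)
            record("simulate", sdir)

        if "decode" in config.stages:
            _log("decode", "cross-validating dann and bayes decoders")
            ens = build_ensemble(session, profile="coarse")
            for method in ("dann", "bayes"):
                cv = crossvalidate(
                    session, method=method, n_sets=config.n_sets_decode,
                    seed=config.seeds["decode"], ensemble=ens,
                    train_config=train_config,
                )
                results[f"cv_{method}"] = cv
                rows = []
                for path in cv["paths"]:
                    rows.append(pd.DataFrame({
                        "t": path.t, "x_pred": path.pred[:, 0],
                        "y_pred": path.pred[:, 1], "x_true": path.actual[:, 0],
                        "y_true": path.actual[:, 1], "err_cm": path.error,
                    }))
                p_csv = out / f"decoded_{method}.csv"
                pd.concat(rows).to_csv(p_csv, index=False)
                p_json = out / f"decode_{method}_summary.json"
                _write_json(p_json, {
                    "rmse_mean": cv["rmse_mean"], "rmse_sd": cv["rmse_sd"],
                    "median_mean": cv["median_mean"], "median_sd": cv["median_sd"],
                    "sets": cv["sets"],
                })
                record(f"decode:{method}", p_csv, p_json)
            emap = error_map(results=[results["cv_dann"]],
                             bounds=session.geometry.bounds)
            p = out / "error_map.json"
            _write_json(p, {"mean": emap["mean"], "max": emap["max"],
                            "shape": emap["shape"]})
            record("decode:error_map", p)

        if "excursions" in config.stages:
            _log("excursions", f"detecting with method={config.detect_method}")
            fine = build_ensemble(session, profile="fine")
            det = detect_excursion_trials(
                session, seed=config.seeds["excursions"],
                method=config.detect_method, n_sets=config.n_sets_detect,
                train_config=train_config, ensemble=fine,
            )
            results["detection"] = det
            results["fine_ensemble"] = fine
            ev_rows = [{
                "trial": e.trial_index, "feeder": e.occupied_feeder,
                "onset": e.onset, "offset": e.offset,
                "duration_ms": e.duration_ms, "peak_err_cm": e.peak_error_cm,
                "endpoint_x": e.endpoint[0], "endpoint_y": e.endpoint[1],
                "endpoint_label": e.endpoint_feeder or "none",
                "set_index": e.set_index,
            } for e in det["events"]]
            p_csv = out / "excursion_events.csv"
            pd.DataFrame(ev_rows).to_csv(p_csv, index=False)
            extras = {}
            if det["events"]:
                extras["endpoint_chi2"] = endpoint_concentration_test(
                    det["events"], session.geometry)
                al = align_onsets(det["events"], session)
                extras["onsets_rel_activation"] = al["relative_to_activation"]
                extras["onsets_rel_zone_exit"] = al["relative_to_zone_exit"]
            rec = preference_record(session, det["events"])
            results["preference_record"] = rec
            p_json = out / "excursions_summary.json"
            _write_json(p_json, {
                "n_flagged": int(sum(det["flags"].values())),
                "flag_fraction": {str(k): v for k, v in det["flag_fraction"].items()},
                "preference_right": rec.preference_right,
                "excursion_freq_right": rec.excursion_freq_right,
                **extras,
            })
            record("excursions", p_csv, p_json)

        if "encoding" in config.stages:
            _log("encoding", "informative cells, excursion cells, classifier")
            seed = config.seeds["encoding"]
            rows = []
            profiles = {}
            for target in ("reward", "choice"):
                prof = informative_cells(session, target=target, seed=seed,
                                         n_sets=config.n_sets_lasso)
                profiles[target] = prof
                for u, f, c in zip(prof.unit_ids, prof.frequency[target],
                                   prof.category[target]):
                    rows.append({"unit_id": u, "attribute": target,
                                 "frequency": f, "category": c})
            if "detection" in results and results["detection"]["events"]:
                prof = excursion_related_cells(
                    session, results["detection"], results["fine_ensemble"])
                for attr in prof.frequency:
                    for u, f, c in zip(prof.unit_ids, prof.frequency[attr],
                                       prof.category[attr]):
                        rows.append({"unit_id": u, "attribute": attr,
                                     "frequency": f, "category": c})
            p_csv = out / "cell_info.csv"
            pd.DataFrame(rows).to_csv(p_csv, index=False)
            results["cell_info"] = rows

            mats = feeder_classifier_all(
                session, seed=seed, n_reps=config.n_reps_classifier,
                train_config=train_config,
            )
            results["confusion"] = mats
            p_json = out / "confusion_matrices.json"
            _write_json(p_json, {
                v: {"matrix": m.matrix, "accuracy": m.accuracy}
                for v, m in mats.items()
            })
            record("encoding", p_csv, p_json)

        if "report" in config.stages:
            paths = make_report(results, out)
            record("report", *paths)
    except Exception as e:
        stage = manifest["stages"][-1] if manifest["stages"] else "setup"
        _write_json(out / "manifest.json", manifest)
        raise StageError(f"pipeline failed after stage '{stage}': {e}") from e

    manifest["finished"] = time.strftime("%Y-%m-%dT%H:%M:%S")
    _write_json(out / "manifest.json", manifest)
    manifest["outputs"].append(str(out / "manifest.json"))
    return manifest


def report_from_dir(run_dir) -> list[Path]:
    """Rebuild the per-figure summary tables from a completed run directory."""
    run_dir = Path(run_dir)
    rdir = run_dir / "report"
    rdir.mkdir(parents=True, exist_ok=True)
    written, notes = [], []

    rows = []
    for method in ("dann", "bayes"):
        p = run_dir / f"decode_{method}_summary.json"
        if p.exists():
            d = json.loads(p.read_text())
            rows.append({"method": method, "rmse_mean": d["rmse_mean"],
                         "rmse_sd": d["rmse_sd"],
                         "median_mean": d["median_mean"]})
    if rows:
        pd.DataFrame(rows).to_csv(rdir / "rmse_by_method.csv", index=False)
        written.append(rdir / "rmse_by_method.csv")
    else:
        notes.append("rmse_by_method.csv: decode summaries missing, skipped")

    ev_path = run_dir / "excursion_events.csv"
    if ev_path.exists():
        ev = pd.read_csv(ev_path)
        if len(ev):
            d = ev["duration_ms"].to_numpy()
            counts, edges = np.histogram(d, bins=np.arange(0, d.max() + 40, 20))
            pd.DataFrame({"bin_left_ms": edges[:-1], "count": counts}).to_csv(
                rdir / "excursion_duration_hist.csv", index=False)
            ev[["onset", "feeder"]].to_csv(rdir / "excursion_onsets.csv",
                                           index=False)
            written += [rdir / "excursion_duration_hist.csv",
                        rdir / "excursion_onsets.csv"]
    else:
        notes.append("excursion tables: events missing, skipped")

    cm_path = run_dir / "confusion_matrices.json"
    if cm_path.exists():
        mats = json.loads(cm_path.read_text())
        rows = []
        labels = ("L", "R", "C")
        for v, d in mats.items():
            for i, true in enumerate(labels):
                for j, pred in enumerate(labels):
                    rows.append({"variant": v, "true": true, "pred": pred,
                                 "p": d["matrix"][i][j]})
        pd.DataFrame(rows).to_csv(rdir / "confusion_matrices.csv", index=False)
        written.append(rdir / "confusion_matrices.csv")

    ci_path = run_dir / "cell_info.csv"
    if ci_path.exists():
        pd.read_csv(ci_path).to_csv(rdir / "cell_informativeness.csv",
                                    index=False)
        written.append(rdir / "cell_informativeness.csv")

    (rdir / "notes.txt").write_text(
        "\n".join(notes) + "\n" if notes else "all available tables rebuilt\n")
    written.append(rdir / "notes.txt")
    return written


def make_report(results: dict, out: Path) -> list[Path]:
    """Per-figure summary tables from pipeline outputs; missing inputs are noted."""
    out = Path(out)
    rdir = out / "report"
    rdir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    notes: list[str] = []

    def table(name, fn):
        try:
            fn()
            written.append(rdir / name)
        except KeyError:
            notes.append(f"{name}: upstream output missing, skipped")

    def rmse_table():
        rows = [{"method": m, "rmse_mean": results[f"cv_{m}"]["rmse_mean"],
                 "rmse_sd": results[f"cv_{m}"]["rmse_sd"],
                 "median_mean": results[f"cv_{m}"]["median_mean"]}
                for m in ("dann", "bayes")]
        pd.DataFrame(rows).to_csv(rdir / "rmse_by_method.csv", index=False)

    def error_by_zone():
        cv = results["cv_dann"]
        rows = []
        for path in cv["paths"]:
            rows.append(pd.DataFrame({"err_cm": path.error,
                                      "trial": path.trial_index}))
        pd.concat(rows).to_csv(rdir / "error_by_position.csv", index=False)

    def duration_hist():
        ev = results["detection"]["events"]
        if not ev:
            raise KeyError("events")
        d = np.array([e.duration_ms for e in ev])
        counts, edges = np.histogram(d, bins=np.arange(0, d.max() + 40, 20))
        pd.DataFrame({"bin_left_ms": edges[:-1], "count": counts}).to_csv(
            rdir / "excursion_duration_hist.csv", index=False)

    def onset_table():
        ev = results["detection"]["events"]
        if not ev:
            raise KeyError("events")
        pd.DataFrame({"onset": [e.onset for e in ev],
                      "feeder": [e.occupied_feeder for e in ev]}).to_csv(
            rdir / "excursion_onsets.csv", index=False)

    def confusion_table():
        mats = results["confusion"]
        rows = []
        for v, m in mats.items():
            for i, true in enumerate(m.labels):
                for j, pred in enumerate(m.labels):
                    rows.append({"variant": v, "true": true, "pred": pred,
                                 "p": m.matrix[i, j]})
        pd.DataFrame(rows).to_csv(rdir / "confusion_matrices.csv", index=False)

    def preference_table():
        rec = results["preference_record"]
        pd.DataFrame([{"preference_right": rec.preference_right,
                       "excursion_freq_right": rec.excursion_freq_right}]).to_csv(
            rdir / "preference_vs_excursions.csv", index=False)

    def cell_info_table():
        pd.DataFrame(results["cell_info"]).to_csv(
            rdir / "cell_informativeness.csv", index=False)

    table("rmse_by_method.csv", rmse_table)
    table("error_by_position.csv", error_by_zone)
    table("excursion_duration_hist.csv", duration_hist)
    table("excursion_onsets.csv", onset_table)
    table("confusion_matrices.csv", confusion_table)
    table("preference_vs_excursions.csv", preference_table)
    table("cell_informativeness.csv", cell_info_table)
    (rdir / "notes.txt").write_text("\n".join(notes) + "\n" if notes else "all tables present\n")
    written.append(rdir / "notes.txt")
    return written
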