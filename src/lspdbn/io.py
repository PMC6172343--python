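"""Readers, writers, run configuration and the end-to-end pipeline.

Trials travel as one delimited numeric matrix per trial (rows = channels)
plus a JSON metadata sidecar carrying the sampling rate, labels and the
generator configuration.  EDF reading is available through mne when that
package is installed.  `run_pipeline` ties the whole chain together --
simulate/read, filter, segment, remove, extract, normalize, train,
evaluate -- and writes a manifest so any run can be reproduced from its
seed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import tempfile
from dataclasses import dataclass, field
from pathlib import Path
from typing import List, Optional, Sequence, Tuple

import numpy as np
import yaml

from . import __version__
from ._utils import derive_seed
from .baselines import SvmConfig
from .dbn import DBNModel, RBMParams, TrainConfig
from .evaluate import (HARNESS_DBN_CONFIG, DEFAULT_RATIOS, RemovalCurve,
                       SplitSpec, run_removal_curve)
from .preprocess import FilterSpec, RemovalSpec, WindowSpec
from .spectral import SubbandSpec
from .synth import MotorImageryConfig, Trial, generate_dataset

__all__ = [
    "write_trials",
    "read_trials",
    "read_trials_edf",
    "save_model",
    "load_model",
    "RunConfig",
    "run_pipeline",
]


# ---------------------------------------------------------------------------
# Trial interchange: delimited matrices + JSON sidecar


def write_trials(trials: Sequence[Trial], directory: str | Path) -> Path:
    """Write one CSV matrix per trial (rows = channels) plus metadata.json."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    meta = {"sampling_rate": trials[0].sampling_rate,
            "subject_id": trials[0].subject_id,
            "trials": []}
    for trial in trials:
        name = f"trial_{trial.trial_id:05d}.csv"
        _atomic_write_text(
            directory / name,
            "\n".join(",".join(f"{v:.10g}" for v in row) for row in trial.data) + "\n")
        meta["trials"].append({"file": name, "trial_id": trial.trial_id,
                               "label": trial.label})
    _atomic_write_text(directory / "metadata.json", json.dumps(meta, indent=1))
    return directory


def read_trials(path: str | Path) -> List[Trial]:
    """Read trials written by :func:`write_trials`.

    Parse errors name the offending file and location.
    """
    directory = Path(path)
    meta_path = directory / "metadata.json"
    if not meta_path.exists():
        raise FileNotFoundError(f"no metadata.json in {directory}")
    meta = json.loads(meta_path.read_text())
    trials = []
    for entry in meta["trials"]:
        fpath = directory / entry["file"]
        rows = []
        for lineno, line in enumerate(fpath.read_text().splitlines(), start=1):
            if not line.strip():
                continue
            fields = line.split(",")
            try:
                rows.append([float(tok) for tok in fields])
            except ValueError:
                bad = next(tok for tok in fields
                           if not _is_number(tok))
                col = fields.index(bad) + 1
                raise ValueError(
                    f"{fpath}: non-numeric token {bad!r} at row {lineno}, "
                    f"column {col}") from None
        lengths = {len(r) for r in rows}
        if len(lengths) != 1:
            raise ValueError(f"{fpath}: ragged rows (lengths {sorted(lengths)})")
        trials.append(Trial(data=np.asarray(rows),
                            sampling_rate=meta["sampling_rate"],
                            label=int(entry["label"]),
                            trial_id=int(entry["trial_id"]),
                            subject_id=meta.get("subject_id", "unknown")))
    return trials


def _is_number(tok: str) -> bool:
    try:
        float(tok)
        return True
    except ValueError:
        return False


def read_trials_edf(paths: Sequence[str | Path],
                    labels: Sequence[int]) -> List[Trial]:
    """Read one trial per EDF file (requires the optional mne dependency).

    All channels of a file must share one sampling rate; mismatches are
    rejected with a message naming the file.
    """
    try:
        import mne
    except ImportError as exc:  # pragma: no cover - depends on extras
        raise ImportError("EDF reading requires the 'mne' package "
                          "(install lspdbn[edf])") from exc
    if len(paths) != len(labels):
        raise ValueError("need one label per EDF file")
    trials = []
    for i, (path, label) in enumerate(zip(paths, labels)):
        raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
        rates = {raw.info["sfreq"]}
        if len(rates) != 1:
            raise ValueError(f"{path}: channels disagree on sampling rate")
        trials.append(Trial(data=raw.get_data(), sampling_rate=float(raw.info["sfreq"]),
                            label=int(label), trial_id=i,
                            subject_id=Path(path).stem))
    return trials


# ---------------------------------------------------------------------------
# Model serialization


def save_model(model: DBNModel, path: str | Path) -> Path:
    """Serialize a DBN (all parameter blocks + config echo) to one .npz file."""
    path = Path(path)
    arrays = {}
    for i, rbm in enumerate(model.rbms):
        arrays[f"rbm{i}_weights"] = rbm.weights
        arrays[f"rbm{i}_visible_bias"] = rbm.visible_bias
        arrays[f"rbm{i}_hidden_bias"] = rbm.hidden_bias
    arrays["softmax_weights"] = model.softmax_weights
    arrays["softmax_bias"] = model.softmax_bias
    meta = {"layer_sizes": list(model.layer_sizes),
            "class_count": model.class_count,
            "pretrained": model.pretrained,
            "finetuned": model.finetuned,
            "n_rbms": len(model.rbms),
            "config": dataclasses.asdict(model.config) if model.config else None,
            "version": __version__}
    arrays["meta_json"] = np.frombuffer(
        json.dumps(meta).encode(), dtype=np.uint8)
    np.savez(path, **arrays)
    return path


def load_model(path: str | Path) -> DBNModel:
    with np.load(path) as data:
        meta = json.loads(bytes(data["meta_json"]).decode())
        rbms = [RBMParams(weights=data[f"rbm{i}_weights"],
                          visible_bias=data[f"rbm{i}_visible_bias"],
                          hidden_bias=data[f"rbm{i}_hidden_bias"])
                for i in range(meta["n_rbms"])]
        config = TrainConfig(**meta["config"]) if meta["config"] else None
        return DBNModel(rbms=rbms,
                        softmax_weights=data["softmax_weights"],
                        softmax_bias=data["softmax_bias"],
                        layer_sizes=tuple(meta["layer_sizes"]),
                        class_count=meta["class_count"],
                        pretrained=meta["pretrained"],
                        finetuned=meta["finetuned"],
                        config=config)


# ---------------------------------------------------------------------------
# Full pipeline


@dataclass
class RunConfig:
    """Everything one experiment needs; every stage seed derives from ``seed``."""

    mi: MotorImageryConfig = field(default_factory=MotorImageryConfig)
    trials_per_class: int = 20
    filter: FilterSpec = field(default_factory=FilterSpec)
    window: WindowSpec = field(default_factory=WindowSpec)
    removal: RemovalSpec = field(default_factory=RemovalSpec)
    bands: SubbandSpec = field(default_factory=SubbandSpec)
    split: SplitSpec = field(default_factory=SplitSpec)
    dbn: TrainConfig = HARNESS_DBN_CONFIG
    dbn_hidden: Tuple[int, ...] = (60, 50, 35)
    svm: SvmConfig = field(default_factory=SvmConfig)
    estimators: Tuple[str, ...] = ("lsp", "fft", "welch")
    classifiers: Tuple[str, ...] = ("dbn",)
    forms: Tuple[str, ...] = ("point", "chunk")
    ratios: Tuple[float, ...] = DEFAULT_RATIOS
    n_seeds: int = 3
    seed: int = 0
    input_dir: Optional[str] = None
    output_dir: str = "lspdbn_results"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        kwargs = {}
        nested = {"mi": MotorImageryConfig, "filter": FilterSpec,
                  "window": WindowSpec, "removal": RemovalSpec,
                  "bands": SubbandSpec, "split": SplitSpec,
                  "dbn": TrainConfig, "svm": SvmConfig}
        for key, value in raw.items():
            if key in nested:
                if nested[key] is MotorImageryConfig and "affected_channel_map" in value:
                    value["affected_channel_map"] = {
                        int(k): tuple(v) for k, v in value["affected_channel_map"].items()}
                kwargs[key] = nested[key](**value)
            elif key in ("estimators", "classifiers", "forms", "ratios", "dbn_hidden"):
                kwargs[key] = tuple(value)
            else:
                kwargs[key] = value
        return cls(**kwargs)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["mi"]["affected_channel_map"] = {
            int(k): list(v) for k, v in d["mi"]["affected_channel_map"].items()}
        return d


@dataclass
class PipelineResult:
    curve: RemovalCurve
    manifest: dict
    output_dir: Path


def _atomic_write_text(path: Path, text: str) -> None:
    """Write via a temp file + rename so aborted runs leave no partial files."""
    path.parent.mkdir(parents=True, exist_ok=True)
    with tempfile.NamedTemporaryFile("w", dir=path.parent, delete=False,
                                     suffix=".tmp") as handle:
        handle.write(text)
        tmp = Path(handle.name)
    tmp.replace(path)


def _sha256(text: str) -> str:
    return hashlib.sha256(text.encode()).hexdigest()


_log = logging.getLogger("lspdbn")


def run_pipeline(config: RunConfig) -> PipelineResult:
    """Execute the full chain and write results + manifest to the output dir."""
    if config.input_dir:
        trials = read_trials(config.input_dir)
        _log.info("read %d trials from %s", len(trials), config.input_dir)
    else:
        data_seed = derive_seed(config.seed, 0xDA7A)
        trials = generate_dataset(config.mi, config.trials_per_class, data_seed)
        _log.info("generated %d trials (%d channels, seed %d)",
                  len(trials), config.mi.n_channels, data_seed)
    _log.info("evaluating %s x %s x %s at ratios %s, %d seeds (seed %d)",
              config.estimators, config.classifiers, config.forms,
              config.ratios, config.n_seeds, config.seed)
    curve = run_removal_curve(
        trials, estimators=config.estimators, classifiers=config.classifiers,
        forms=config.forms, ratios=config.ratios, n_seeds=config.n_seeds,
        base_seed=config.seed, filter_spec=config.filter,
        window_spec=config.window, removal=config.removal, bands=config.bands,
        split_spec=config.split, dbn_hidden=config.dbn_hidden,
        dbn_config=config.dbn, svm_config=config.svm)
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    results_csv = curve.results.to_csv(index=False)
    summary_csv = curve.summary().to_csv(index=False)
    _atomic_write_text(out / "results.csv", results_csv)
    _atomic_write_text(out / "summary.csv", summary_csv)
    manifest = {"config": config.to_dict(), "seed": config.seed,
                "version": __version__,
                "n_trials": len(trials),
                "hashes": {"results.csv": _sha256(results_csv),
                           "summary.csv": _sha256(summary_csv)}}
    _atomic_write_text(out / "manifest.json", json.dumps(manifest, indent=1))
    return PipelineResult(curve=curve, manifest=manifest, output_dir=out)
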