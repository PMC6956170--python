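"""Readers/writers and model persistence.

Datasets, signals, features and reports travel as delimited text (comma
by default, tab accepted); models and annotations as JSON.  The model
record stores support vectors, dual coefficients and biases at full float
repr precision, so a save/load round trip reproduces decision values
exactly.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .base_svm import LabeledDataset, PairwiseMachine, SVMModel
from .kernels import KernelSpec
from .lsa_svm import LabelEncoding
from .sa_svm import AdvisedModel, MisclassifiedSet

__all__ = ["read_tabular", "write_tabular", "save_model", "load_model",
           "read_recording", "write_recording"]

logger = logging.getLogger("lsasvm")

SCHEMA_VERSION = 1


def read_tabular(path, label_col: str, delimiter: str = ",") -> LabeledDataset:
    """Load a UCI-style delimited table: numeric features plus one label
    column.  Rows with non-finite or non-numeric features are dropped with
    a logged count."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such dataset file: {path}")
    df = pd.read_csv(path, delimiter=delimiter)
    if label_col not in df.columns:
        raise ValueError(
            f"label column {label_col!r} not found; columns: {list(df.columns)}")
    y = df[label_col].to_numpy()
    feats = df.drop(columns=[label_col]).apply(pd.to_numeric, errors="coerce")
    ok = np.isfinite(feats.to_numpy(dtype=float)).all(axis=1)
    dropped = int((~ok).sum())
    if dropped:
        logger.warning("dropped %d row(s) with non-numeric/non-finite features", dropped)
    if not ok.any():
        raise ValueError(f"no usable rows in {path}")
    ds = LabeledDataset(feats.to_numpy(dtype=float)[ok], y[ok])
    ds.metadata.update(feature_names=list(feats.columns), dropped_rows=dropped,
                       source=str(path))
    logger.info("read %d rows, %d features, classes=%s", ds.n, ds.d, ds.classes)
    return ds


def write_tabular(ds: LabeledDataset, path, label_col: str = "label",
                  delimiter: str = ",") -> None:
    names = ds.metadata.get("feature_names") or [f"f{i}" for i in range(ds.d)]
    df = pd.DataFrame(ds.X, columns=names)
    df[label_col] = ds.y
    df.to_csv(path, sep=delimiter, index=False)


def read_recording(data_path, sidecar_path):
    """Signal matrix (one column per channel, header row) plus a JSON
    sidecar {rate_hz, annotations: [[label, start, end], ...]}."""
    from .emg import SignalRecording
    df = pd.read_csv(data_path)
    with open(sidecar_path) as fh:
        side = json.load(fh)
    n = len(df)
    ann = np.full(n, side.get("rest_label", "rest"), dtype=object)
    for label, start, end in side.get("annotations", []):
        ann[start:end] = label
    return SignalRecording(data=df.to_numpy(dtype=float).T, rate=side["rate_hz"],
                           channel_names=list(df.columns), annotations=ann,
                           rest_label=side.get("rest_label", "rest"))


def write_recording(rec, data_path, sidecar_path) -> None:
    pd.DataFrame(rec.data.T, columns=rec.channel_names).to_csv(data_path, index=False)
    runs = []
    if rec.annotations is not None:
        start = 0
        for i in range(1, rec.n_samples + 1):
            if i == rec.n_samples or rec.annotations[i] != rec.annotations[start]:
                if rec.annotations[start] != rec.rest_label:
                    runs.append([str(rec.annotations[start]), int(start), int(i)])
                start = i
    with open(sidecar_path, "w") as fh:
        json.dump({"rate_hz": rec.rate, "rest_label": str(rec.rest_label),
                   "annotations": runs}, fh)


def _machine_dict(m: PairwiseMachine) -> dict:
    return {"neg_class": m.neg_class, "pos_class": m.pos_class,
            "support_vectors": m.support_vectors.tolist(),
            "dual_coefs": m.dual_coefs.tolist(), "bias": m.bias}


def _model_dict(model: SVMModel) -> dict:
    return {"variant": model.variant, "kernel": model.kernel.to_dict(),
            "C_or_nu": model.C_or_nu, "classes": list(model.classes),
            "multiclass_scheme": model.multiclass_scheme,
            "machines": [_machine_dict(m) for m in model.machines]}


def _model_from_dict(d: dict) -> SVMModel:
    machines = [PairwiseMachine(
        neg_class=m["neg_class"], pos_class=m["pos_class"],
        support_vectors=np.asarray(m["support_vectors"], dtype=float),
        dual_coefs=np.asarray(m["dual_coefs"], dtype=float),
        bias=float(m["bias"])) for m in d["machines"]]
    return SVMModel(variant=d["variant"], kernel=KernelSpec.from_dict(d["kernel"]),
                    C_or_nu=d["C_or_nu"], classes=list(d["classes"]),
                    machines=machines, multiclass_scheme=d["multiclass_scheme"])


def save_model(model, path) -> None:
    """Serialize an SVMModel or AdvisedModel to a single JSON document."""
    doc: dict = {"schema_version": SCHEMA_VERSION}
    if isinstance(model, AdvisedModel):
        doc["type"] = "advised"
        doc["base"] = _model_dict(model.base)
        nl = [None if not np.isfinite(v) else v for v in model.md.nl]
        doc["advising"] = {
            "space": model.space,
            "normalization": model.normalization,
            "md": {"indices": model.md.indices.tolist(),
                   "points": model.md.points.tolist(),
                   "labels": model.md.labels.tolist(), "nl": nl},
            "label_encoding": (model.label_encoding.to_dict()
                               if model.label_encoding else None),
            "label_kernel": (model.label_kernel.to_dict()
                             if model.label_kernel else None),
        }
    elif isinstance(model, SVMModel):
        doc["type"] = "svm"
        doc["model"] = _model_dict(model)
    else:
        raise TypeError(f"cannot serialize object of type {type(model).__name__}")
    with open(path, "w") as fh:
        json.dump(doc, fh)


def load_model(path):
    with open(path) as fh:
        try:
            doc = json.load(fh)
        except json.JSONDecodeError as exc:
            raise ValueError(f"model file {path} is not valid JSON "
                             f"(truncated?): {exc}") from exc
    version = doc.get("schema_version")
    if version != SCHEMA_VERSION:
        raise ValueError(f"model schema version {version!r} is not the "
                         f"supported version {SCHEMA_VERSION}")
    if doc["type"] == "svm":
        return _model_from_dict(doc["model"])
    adv = doc["advising"]
    md = adv["md"]
    m = len(md["indices"])
    md_set = MisclassifiedSet(
        indices=np.asarray(md["indices"], dtype=int),
        points=(np.asarray(md["points"], dtype=float)
                if m else np.zeros((0, 0))),
        labels=np.asarray(md["labels"]),
        nl=np.asarray([np.nan if v is None else v for v in md["nl"]], dtype=float))
    enc = adv.get("label_encoding")
    lk = adv.get("label_kernel")
    return AdvisedModel(
        base=_model_from_dict(doc["base"]), md=md_set, space=adv["space"],
        label_encoding=LabelEncoding.from_dict(enc) if enc else None,
        label_kernel=KernelSpec.from_dict(lk) if lk else None,
        normalization=adv.get("normalization", "mean"))
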