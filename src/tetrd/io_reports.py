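"""Trace files, run manifests and comparison reports.

Traces are plain CSV for inspectability: a comment header declaring the
sampling step and label, then one time column and one column per run, written
at full float precision so a round-trip is lossless.  A run manifest is a
JSON record sufficient to reproduce a run byte-identically (seed, ranks,
schedule, mesh/model hashes, event counts).  ``compare_runs`` ties two trace
directories to the statistics module: peak features per run, batched CVM
p-values, the consistently-low-p rejection rule, and the confidence-band
verdict, emitted as one JSON report.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .stats import (TraceSet, ci_band_compare, cvm_batch_compare, cvm_reject,
                    extract_peak_features)

__version__ = "0.1.0"


def write_traces(traces: TraceSet, path) -> None:
    path = Path(path)
    cols = {"time_s": traces.times}
    for i, row in enumerate(traces.data):
        cols[f"run_{i:04d}"] = row
    with open(path, "w") as fh:
        fh.write(f"# dt={traces.dt!r} label={traces.label}\n")
        pd.DataFrame(cols).to_csv(fh, index=False, float_format="%.17g")


def read_traces(path) -> TraceSet:
    path = Path(path)
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("# dt="):
            raise ValueError(f"{path}: missing '# dt=' header line "
                             f"(got {header[:40]!r})")
        fields = dict(p.split("=", 1) for p in header[2:].strip().split(" ", 1))
        dt = float(fields["dt"])
        label = fields.get("label", "")
        df = pd.read_csv(fh, float_precision="round_trip")
    run_cols = [c for c in df.columns if c.startswith("run_")]
    if "time_s" not in df.columns or not run_cols:
        raise ValueError(f"{path}: expected columns time_s, run_*; got {list(df.columns)}")
    t = df["time_s"].to_numpy()
    if len(t) > 1 and not np.allclose(np.diff(t), dt, rtol=1e-9, atol=1e-15):
        raise ValueError(f"{path}: time column does not match declared dt={dt}")
    return TraceSet(dt, df[run_cols].to_numpy().T, label)


def write_manifest(path, *, seed: int, ranks: int, schedule: dict,
                   mesh_hash: str, model_hash: str = "",
                   event_counts=None, extra=None) -> dict:
    doc = {
        "software": f"tetrd {__version__}",
        "seed": seed,
        "ranks": ranks,
        "schedule": schedule,
        "mesh_hash": mesh_hash,
        "model_hash": model_hash,
        "event_counts": event_counts or [],
    }
    if extra:
        doc.update(extra)
    Path(path).write_text(json.dumps(doc, indent=2, sort_keys=True) + "\n")
    return doc


def model_hash(doc: dict) -> str:
    return hashlib.sha256(json.dumps(doc, sort_keys=True).encode()).hexdigest()


def compare_runs(dir_a, dir_b, batch_size: int = 100, level: float = 0.99,
                 min_prominence: float = 0.010, min_separation: float = 0.002,
                 out_path=None) -> dict:
    """Statistical comparison report for two directories of trace CSVs.

    Both directories must contain the same probe file names.  For every probe
    the report holds, per peak index, the summary of the all-pairs batched
    CVM p-values for peak heights and timestamps, the fraction of p < 0.01
    with the consistently-low-p verdict, and the confidence-band verdict on
    the raw traces.
    """
    dir_a, dir_b = Path(dir_a), Path(dir_b)
    names_a = sorted(p.name for p in dir_a.glob("*.csv"))
    names_b = sorted(p.name for p in dir_b.glob("*.csv"))
    if names_a != names_b:
        raise ValueError(f"probe mismatch: {names_a} vs {names_b}")
    if not names_a:
        raise ValueError("no trace files found")
    report: dict = {"probes": {}, "batch_size": batch_size, "ci_level": level}
    for name in names_a:
        ta, tb = read_traces(dir_a / name), read_traces(dir_b / name)
        fa = extract_peak_features(ta, min_prominence, min_separation)
        fb = extract_peak_features(tb, min_prominence, min_separation)
        n_peaks = min(min((len(h) for h in fa.heights), default=0),
                      min((len(h) for h in fb.heights), default=0))
        features = {}
        fracs = []
        for which, geta, getb in (
            ("peak_height", fa.heights, fb.heights),
            ("peak_time", fa.timestamps, fb.timestamps),
        ):
            for k in range(n_peaks):
                sa = np.array([run[k] for run in geta])
                sb = np.array([run[k] for run in getb])
                bs = min(batch_size, len(sa), len(sb))
                p = cvm_batch_compare(sa, sb, bs)
                rej, frac = cvm_reject(p)
                fracs.append(frac)
                features[f"{which}_{k}"] = {
                    "p_median": float(np.median(p)),
                    "frac_below_0.01": frac,
                    "rejected": bool(rej),
                }
        band_rej, band_out = ci_band_compare(ta, tb, level)
        verdict_rejected = band_rej or any(v["rejected"] for v in features.values())
        report["probes"][name] = {
            "n_peaks_compared": n_peaks,
            "features": features,
            "frac_below_0.01_overall": float(np.mean(fracs)) if fracs else 0.0,
            "ci_band": {"rejected": bool(band_rej),
                        "frac_outside": band_out},
            "verdict": "rejected" if verdict_rejected else "not rejected",
        }
    report["verdict"] = ("rejected" if any(
        p["verdict"] == "rejected" for p in report["probes"].values())
        else "not rejected")
    if out_path is not None:
        Path(out_path).write_text(json.dumps(report, indent=2) + "\n")
    return report
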