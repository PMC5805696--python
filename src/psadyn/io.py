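"""Reading and writing the delimited-text and JSON interchange formats.

PSA series travel as two TSV files — observations (patient_id, time_days,
psa_ng_ml) and treatment intervals (patient_id, start_day, end_day,
on_treatment) — so real data in the same layout can replace the synthetic
files.  Ground truth, fit ensembles, and schedules are JSON with sorted
keys, so identical seeds and configs yield byte-identical output.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Dict, Iterable

import pandas as pd

from .classification import PatientType
from .psa_fitting import BootstrapEnsemble, FitResult, PSASeries
from .scheduling import OptimizedSchedule
from .tumor_model import CellState, DailyTransition

__all__ = [
    "write_cohort",
    "read_series",
    "write_ensembles",
    "read_ensembles",
    "write_schedules",
    "read_schedules",
    "write_json",
]


def write_json(obj, path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


def write_cohort(patients: Iterable, outdir, include_truth: bool = True) -> None:
    """Write a synthetic cohort: observed TSVs plus a separate ground-truth JSON.

    The ground-truth file (parameters, types, seeds) is kept apart from the
    "observed" files so blinded pipeline runs are possible.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    patients = list(patients)
    obs = pd.DataFrame(
        [
            (p.patient_id, int(t), float(v))
            for p in patients
            for t, v in zip(p.series.times, p.series.psa)
        ],
        columns=["patient_id", "time_days", "psa_ng_ml"],
    )
    obs.to_csv(outdir / "psa_series.tsv", sep="\t", index=False, float_format="%.6f")
    ivs = pd.DataFrame(
        [
            (p.patient_id, int(s), int(e), int(on))
            for p in patients
            for s, e, on in p.series.intervals
        ],
        columns=["patient_id", "start_day", "end_day", "on_treatment"],
    )
    ivs.to_csv(outdir / "treatment_intervals.tsv", sep="\t", index=False)
    labels = pd.DataFrame(
        [(p.patient_id, p.status, p.gleason) for p in patients],
        columns=["patient_id", "status", "gleason"],
    )
    labels.to_csv(outdir / "labels.tsv", sep="\t", index=False)
    if include_truth:
        truth = {
            p.patient_id: {
                "d": [float(v) for v in p.d.as_vector()],
                "x0": [float(v) for v in p.x0.as_array()],
                "type": p.truth_type.label,
                "seed": int(p.seed),
                "flags": list(p.flags),
            }
            for p in patients
        }
        write_json(truth, outdir / "ground_truth.json")


def read_series(psa_path, intervals_path) -> Dict[str, PSASeries]:
    """Load per-patient series from the observation and interval TSVs."""
    obs = pd.read_csv(psa_path, sep="\t")
    ivs = pd.read_csv(intervals_path, sep="\t")
    out: Dict[str, PSASeries] = {}
    for pid, group in obs.groupby("patient_id", sort=True):
        group = group.sort_values("time_days")
        mine = ivs[ivs.patient_id == pid].sort_values("start_day")
        out[str(pid)] = PSASeries(
            patient_id=str(pid),
            times=group.time_days.to_numpy(dtype=int),
            psa=group.psa_ng_ml.to_numpy(dtype=float),
            intervals=tuple(
                (int(r.start_day), int(r.end_day), bool(r.on_treatment))
                for r in mine.itertuples()
            ),
        )
    return out


def _fit_to_dict(m: FitResult) -> dict:
    return {
        "d": [float(v) for v in m.d.as_vector()],
        "x0": [float(v) for v in m.x0.as_array()],
        "cost": m.cost,
        "end_error": m.end_error,
        "end_state": [float(v) for v in m.end_state.as_array()],
        "replicate": m.replicate,
        "seed": m.seed,
        "converged": m.converged,
    }


def _fit_from_dict(d: dict) -> FitResult:
    return FitResult(
        d=DailyTransition.from_vector(d["d"]),
        x0=CellState.from_array(d["x0"]),
        cost=float(d["cost"]),
        end_error=float(d["end_error"]),
        end_state=CellState.from_array(d["end_state"]),
        replicate=int(d["replicate"]),
        seed=int(d["seed"]),
        converged=bool(d["converged"]),
    )


def write_ensembles(ensembles: Iterable[BootstrapEnsemble], path) -> None:
    payload = {
        e.patient_id: {
            "accept_threshold": e.accept_threshold,
            "members": [_fit_to_dict(m) for m in e.members],
            "accepted": list(e.accepted),
            "types": [t.label for t in e.types] if e.types else None,
        }
        for e in ensembles
    }
    write_json(payload, path)


_LABEL_TO_TYPE = {t.label: t for t in PatientType}


def read_ensembles(path) -> Dict[str, BootstrapEnsemble]:
    payload = json.loads(Path(path).read_text())
    out = {}
    for pid, rec in payload.items():
        ens = BootstrapEnsemble(
            patient_id=pid,
            members=tuple(_fit_from_dict(m) for m in rec["members"]),
            accepted=tuple(rec["accepted"]),
            accept_threshold=float(rec["accept_threshold"]),
        )
        if rec.get("types"):
            ens.types = tuple(_LABEL_TO_TYPE[t] for t in rec["types"])
        out[pid] = ens
    return out


def write_schedules(schedules: Dict[str, OptimizedSchedule], path) -> None:
    payload = {
        pid: {
            "blocks": list(s.blocks),
            "block_days": s.block_days,
            "horizon": s.horizon,
            "worst_case_psa": s.worst_case_psa,
            "n_evaluated": s.n_evaluated,
            "mean_dynamics": s.mean_dynamics,
        }
        for pid, s in schedules.items()
    }
    write_json(payload, path)


def read_schedules(path) -> Dict[str, OptimizedSchedule]:
    payload = json.loads(Path(path).read_text())
    return {
        pid: OptimizedSchedule(
            blocks=tuple(rec["blocks"]),
            block_days=int(rec["block_days"]),
            horizon=int(rec["horizon"]),
            worst_case_psa=float(rec["worst_case_psa"]),
            n_evaluated=int(rec["n_evaluated"]),
            mean_dynamics=bool(rec["mean_dynamics"]),
        )
        for pid, rec in payload.items()
    }
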