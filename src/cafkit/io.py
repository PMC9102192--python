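"""Readers and writers for the pipeline's file formats.

All tables are headered UTF-8 CSV with "." decimals; images are 8-bit
RGB PNG with ROI masks as single-channel PNG (255 = inside); force
curves are two-column tab-separated text (height_um, force_nN) with
"#"-prefixed metadata header lines; planted truth goes to JSON.
"""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image

from .biomech import ForceCurve
from .subtype import PatientRecord
from .synthetic import SimOutput, TruthBundle, cohort_frame

try:  # Python 3.9+: stdlib package-data access
    from importlib.resources import files as _pkg_files
except ImportError:  # pragma: no cover
    _pkg_files = None


# ---------------------------------------------------------------------------
# Packaged Table 1 fixture
# ---------------------------------------------------------------------------

def load_table1() -> dict:
    """Clinico-pathological cross-tabulations of the 55-patient cohort.

    Returns a mapping factor → {"levels", "subtype_counts",
    "cluster_counts"} with subtype columns ordered AT, BA, CL, ME and
    cluster columns 1, 2.
    """
    text = (_pkg_files("cafkit") / "data" / "table1.json").read_text("utf-8")
    return json.loads(text)


def table1_label_pairs(factor: str, by: str = "subtype") -> tuple[list, list]:
    """Expand a Table 1 cross-tabulation into per-patient label pairs.

    Returns ``(factor_levels, group_labels)`` lists of length N; the
    counts fully determine the label multiset, and downstream
    cross-tabulation is order-invariant.
    """
    t1 = load_table1()
    entry = t1[factor]
    group_names = ["AT", "BA", "CL", "ME"] if by == "subtype" else ["1", "2"]
    counts = entry[f"{by}_counts"]
    fac, lab = [], []
    for level, row in zip(entry["levels"], counts):
        for g, n in zip(group_names, row):
            fac.extend([level] * n)
            lab.extend([g] * n)
    return fac, lab


# ---------------------------------------------------------------------------
# CSV tables
# ---------------------------------------------------------------------------

def write_cohort_csv(cohort: list[PatientRecord], path) -> None:
    cohort_frame(cohort).to_csv(path, encoding="utf-8")


def read_cohort_csv(path) -> list[PatientRecord]:
    df = pd.read_csv(path, index_col="id")
    gene_cols = [c for c in df.columns if c.isupper()]
    clinical_cols = [c for c in ("gender", "site", "pN", "stage")
                     if c in df.columns]
    out = []
    for pid, row in df.iterrows():
        out.append(
            PatientRecord(
                id=str(pid),
                expr={g: float(row[g]) for g in gene_cols},
                smoking=int(row["smoking"]),
                p16=int(row["p16"]),
                clinical={c: str(row[c]) for c in clinical_cols},
                survival_time=float(row["time"]) if "time" in df.columns else None,
                event=int(row["event"]) if "event" in df.columns else None,
            )
        )
    return out


def write_table_csv(df: pd.DataFrame, path, index: bool = False) -> None:
    df.to_csv(path, index=index, encoding="utf-8")


def read_rtdc_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    for col in ("area_um2", "deformation", "porosity"):
        if col not in df.columns:
            raise ValueError(f"RT-DC table missing column {col!r}")
    return df


def read_qpcr_csv(path) -> pd.DataFrame:
    return pd.read_csv(path)


# ---------------------------------------------------------------------------
# Images
# ---------------------------------------------------------------------------

def write_rgb_png(image: np.ndarray, path) -> None:
    Image.fromarray(np.asarray(image, dtype=np.uint8), mode="RGB").save(path)


def read_rgb_png(path) -> np.ndarray:
    return np.asarray(Image.open(path).convert("RGB"))


def write_mask_png(mask: np.ndarray, path) -> None:
    Image.fromarray(
        np.where(np.asarray(mask, dtype=bool), 255, 0).astype(np.uint8),
        mode="L",
    ).save(path)


def read_mask_png(path) -> np.ndarray:
    return np.asarray(Image.open(path).convert("L")) >= 128


# ---------------------------------------------------------------------------
# Force curves
# ---------------------------------------------------------------------------

def write_force_curve(curve: ForceCurve, path) -> None:
    lines = [f"# {k}: {v}" for k, v in sorted(curve.meta.items())]
    lines.append("# columns: height_um\tforce_nN")
    for z, f in zip(curve.height_um, curve.force_nN):
        lines.append(f"{z:.6f}\t{f:.6f}")
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def read_force_curve(path) -> ForceCurve:
    meta: dict = {}
    heights, forces = [], []
    for line in Path(path).read_text(encoding="utf-8").splitlines():
        line = line.strip()
        if not line:
            continue
        if line.startswith("#"):
            body = line[1:].strip()
            if ":" in body:
                k, v = body.split(":", 1)
                if k.strip() != "columns":
                    try:
                        meta[k.strip()] = float(v)
                    except ValueError:
                        meta[k.strip()] = v.strip()
            continue
        z, f = line.split("\t")
        heights.append(float(z))
        forces.append(float(f))
    return ForceCurve(
        height_um=np.asarray(heights), force_nN=np.asarray(forces), meta=meta
    )


# ---------------------------------------------------------------------------
# Whole simulation output
# ---------------------------------------------------------------------------

def write_truth_json(truth: TruthBundle, path) -> None:
    Path(path).write_text(
        json.dumps(asdict(truth), indent=1, sort_keys=True), encoding="utf-8"
    )


def write_simulation(sim: SimOutput, outdir) -> None:
    """Write every generated input under ``outdir`` in its on-disk format."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    write_cohort_csv(sim.cohort, out / "cohort.csv")
    surv = cohort_frame(sim.cohort)[["time", "event"]]
    surv.to_csv(out / "survival.csv", encoding="utf-8")
    sim.qpcr.to_csv(out / "qpcr.csv", index=False, encoding="utf-8")
    sim.rtdc_events.to_csv(out / "rtdc_events.csv", index=False, encoding="utf-8")
    img_dir = out / "colony"
    img_dir.mkdir(exist_ok=True)
    write_rgb_png(sim.colony.reference, img_dir / "reference.png")
    write_mask_png(sim.colony.roi, img_dir / "roi.png")
    for name, img in sim.colony.images.items():
        write_rgb_png(img, img_dir / f"{name}.png")
    fd_dir = out / "force_curves"
    fd_dir.mkdir(exist_ok=True)
    for k, curve in enumerate(sim.force_curves):
        write_force_curve(curve, fd_dir / f"curve_{k:04d}.txt")
    write_truth_json(sim.truth, out / "truth.json")
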