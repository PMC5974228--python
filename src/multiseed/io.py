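"""Reading and writing pipeline artifacts.

Volumes travel as NIfTI-1 (via nibabel): the atlas as an integer label
volume, BOLD series as 4D floats with the repetition time in the 4th
zoom.  Connectivity matrices are CSV with a region-id header and a
``#``-comment metadata line; study manifests are plain TSV tables
(subject, group, session, path).
"""

from __future__ import annotations

import csv
from pathlib import Path

import nibabel as nib
import numpy as np

from .synthdata import StudySet, SubjectScan
from .types import BoldSeries, ConnectivityMatrix, LabelAtlas

__all__ = [
    "save_atlas",
    "load_atlas",
    "save_series",
    "load_series",
    "save_matrix",
    "load_matrix",
    "save_study",
    "load_manifest",
]


def _affine(voxel_size) -> np.ndarray:
    return np.diag([*voxel_size, 1.0])


def save_atlas(atlas: LabelAtlas, path: str | Path) -> Path:
    path = Path(path)
    img = nib.Nifti1Image(atlas.labels.astype(np.int16), _affine(atlas.voxel_size))
    nib.save(img, str(path))
    return path


def load_atlas(path: str | Path) -> LabelAtlas:
    img = nib.load(str(path))
    labels = np.asarray(img.dataobj).astype(np.int32)
    voxel_size = tuple(float(z) for z in img.header.get_zooms()[:3])
    return LabelAtlas(labels=labels, voxel_size=voxel_size)


def save_series(series: BoldSeries, path: str | Path) -> Path:
    path = Path(path)
    img = nib.Nifti1Image(series.data.astype(np.float32), _affine(series.voxel_size))
    img.header.set_zooms((*series.voxel_size, series.tr))
    img.header.set_xyzt_units(xyz="mm", t="sec")
    nib.save(img, str(path))
    return path


def load_series(path: str | Path, brain_mask: np.ndarray | None = None) -> BoldSeries:
    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=float)
    zooms = img.header.get_zooms()
    return BoldSeries(
        data=data,
        tr=float(zooms[3]) if len(zooms) > 3 else 1.0,
        voxel_size=tuple(float(z) for z in zooms[:3]),
        brain_mask=brain_mask,
    )


def save_matrix(matrix: ConnectivityMatrix, path: str | Path) -> Path:
    path = Path(path)
    meta = (
        f"# directed={matrix.directed} scale={matrix.scale} "
        f"fdr_q={matrix.fdr_q} fdr_threshold_r={matrix.fdr_threshold_r}\n"
    )
    with open(path, "w", newline="") as fh:
        fh.write(meta)
        writer = csv.writer(fh)
        writer.writerow(["region"] + [str(int(r)) for r in matrix.region_ids])
        for rid, row in zip(matrix.region_ids, matrix.values):
            writer.writerow([str(int(rid))] + [repr(float(v)) for v in row])
    return path


def load_matrix(path: str | Path) -> ConnectivityMatrix:
    path = Path(path)
    with open(path) as fh:
        meta_line = fh.readline().strip().lstrip("# ")
        meta = dict(item.split("=", 1) for item in meta_line.split())
        reader = csv.reader(fh)
        header = next(reader)
        region_ids = np.array([int(r) for r in header[1:]])
        values = np.array([[float(v) for v in row[1:]] for row in reader])

    def _opt_float(s: str) -> float | None:
        return None if s == "None" else float(s)

    return ConnectivityMatrix(
        values=values,
        directed=(meta["directed"] == "True"),
        scale=meta["scale"],
        fdr_q=_opt_float(meta["fdr_q"]),
        fdr_threshold_r=_opt_float(meta["fdr_threshold_r"]),
        region_ids=region_ids,
    )


def save_study(study: StudySet, outdir: str | Path) -> Path:
    """Write a study to disk: atlas, one NIfTI per scan, and a TSV manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    save_atlas(study.atlas, outdir / "atlas.nii.gz")
    manifest_path = outdir / "manifest.tsv"
    with open(manifest_path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t")
        writer.writerow(["subject", "group", "session", "path"])
        for scan in study.subjects:
            fname = f"{scan.subject_id}_{scan.session}.nii.gz"
            save_series(scan.series, outdir / fname)
            writer.writerow([scan.subject_id, scan.group, scan.session, fname])
    return manifest_path


def load_manifest(manifest_path: str | Path) -> tuple[LabelAtlas, list[SubjectScan]]:
    """Load a study written by :func:`save_study` (atlas.nii.gz alongside)."""
    manifest_path = Path(manifest_path)
    base = manifest_path.parent
    atlas = load_atlas(base / "atlas.nii.gz")
    mask = atlas.foreground_mask()
    scans = []
    with open(manifest_path) as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        for row in reader:
            series = load_series(base / row["path"], brain_mask=mask)
            scans.append(SubjectScan(row["subject"], row["group"], row["session"], series))
    return atlas, scans
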