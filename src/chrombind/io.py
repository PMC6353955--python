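"""File formats: multi-frame TIFF images with JSON sidecars, FRAP trace
CSVs, localization tables, FASTA sequences and TSV annotations."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
from Bio import SeqIO

from .frap import FRAPTrace
from .seqfeat import ProteinRecord


def write_image(path, image: np.ndarray, metadata: dict | None = None) -> None:
    """Write a (multi-frame) grayscale TIFF; metadata goes to a JSON sidecar."""
    path = Path(path)
    tifffile.imwrite(path, np.asarray(image, dtype=np.float32), photometric="minisblack")
    if metadata is not None:
        path.with_suffix(".json").write_text(json.dumps(metadata, indent=2, default=float))


def read_image(path) -> tuple[np.ndarray, dict | None]:
    path = Path(path)
    img = tifffile.imread(path)
    sidecar = path.with_suffix(".json")
    meta = json.loads(sidecar.read_text()) if sidecar.exists() else None
    return img, meta


def write_frap_trace(path, trace: FRAPTrace) -> None:
    pd.DataFrame(
        {"t": trace.t, "roi1": trace.i_roi1, "roi2": trace.i_roi2, "bg": trace.i_bg}
    ).to_csv(path, index=False)


def read_frap_trace(path, n_pre: int) -> FRAPTrace:
    df = pd.read_csv(path)
    return FRAPTrace(
        t=df["t"].to_numpy(),
        i_roi1=df["roi1"].to_numpy(),
        i_roi2=df["roi2"].to_numpy(),
        i_bg=df["bg"].to_numpy(),
        n_pre=n_pre,
    )


def write_localizations(path, locs: pd.DataFrame) -> None:
    locs.to_csv(path, index=False)


def read_localizations(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    required = {"frame", "x", "y"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"localization table missing columns: {sorted(missing)}")
    return df


def read_protein_records(
    fasta_path, annotation_path=None, disorder_path=None, mbf_path=None
) -> list[ProteinRecord]:
    """Assemble protein records from a FASTA file plus optional TSV tables.

    ``annotation_path``: columns tf_id, dbd_start, dbd_end, dbd_family
    (0-based half-open intervals, one row per DBD).  ``disorder_path``:
    columns tf_id, mask (per-residue 0/1 string).  ``mbf_path``: CSV with
    columns tf_id, mbf.
    """
    seqs = {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(fasta_path), "fasta")}
    intervals: dict[str, list] = {}
    if annotation_path is not None:
        ann = pd.read_csv(annotation_path, sep="\t")
        for row in ann.itertuples(index=False):
            intervals.setdefault(row.tf_id, []).append(
                (int(row.dbd_start), int(row.dbd_end), str(row.dbd_family))
            )
    masks: dict[str, np.ndarray] = {}
    if disorder_path is not None:
        dis = pd.read_csv(disorder_path, sep="\t", dtype={"mask": str})
        for row in dis.itertuples(index=False):
            masks[row.tf_id] = np.array([c == "1" for c in row.mask], dtype=bool)
    mbfs: dict[str, float] = {}
    if mbf_path is not None:
        mtab = pd.read_csv(mbf_path)
        mbfs = dict(zip(mtab["tf_id"], mtab["mbf"].astype(float)))
    return [
        ProteinRecord(
            tf_id=tf_id,
            sequence=seq,
            dbd_intervals=intervals.get(tf_id, []),
            disorder_mask=masks.get(tf_id),
            mbf=mbfs.get(tf_id),
        )
        for tf_id, seq in seqs.items()
    ]


def write_protein_records(records: list[ProteinRecord], fasta_path, annotation_path, disorder_path, mbf_path=None) -> None:
    with open(fasta_path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.tf_id}\n{rec.sequence}\n")
    ann_rows = [
        {"tf_id": r.tf_id, "dbd_start": s, "dbd_end": e, "dbd_family": f}
        for r in records
        for s, e, f in r.dbd_intervals
    ]
    pd.DataFrame(ann_rows).to_csv(annotation_path, sep="\t", index=False)
    dis_rows = [
        {"tf_id": r.tf_id, "mask": "".join("1" if b else "0" for b in r.disorder_mask)}
        for r in records
        if r.disorder_mask is not None
    ]
    pd.DataFrame(dis_rows).to_csv(disorder_path, sep="\t", index=False)
    if mbf_path is not None:
        pd.DataFrame(
            [{"tf_id": r.tf_id, "mbf": r.mbf} for r in records if r.mbf is not None]
        ).to_csv(mbf_path, index=False)
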