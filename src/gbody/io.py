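"""Readers and writers for the pipeline's text and TIFF formats.

Writers and readers round-trip losslessly.  Schema violations raise
``ValueError`` naming the file, line and field.  Formats:

* aligned reads — 8-column TSV (chrom, start, end, name, conversion_count,
  strand, read_length, dataset) with an optional ``# total_mapped=N``
  header comment;
* binding sites — BED6+2 (chrom, start, end, name, score, strand, rpm,
  n_conversion_reads);
* gene tables — gene_id-indexed TSV, one column per library;
* qPCR Cq tables and FRAP traces — TSV;
* image stacks — multi-page TIFF with the pixel size (µm) stored in the
  image description (lazily validated: reading succeeds without it, and
  µm-dependent operations fail only when invoked);
* reports and truth records — JSON.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from gbody.enrichment import CqRecord
from gbody.frap import FrapTrace
from gbody.parclip import BindingSite
from gbody.simulate.parclip import READ_COLUMNS

__all__ = [
    "write_reads_tsv",
    "read_reads_tsv",
    "write_sites_bed",
    "read_sites_bed",
    "write_gene_table",
    "read_gene_table",
    "read_cq_table",
    "write_cq_table",
    "write_trace_tsv",
    "read_trace_tsv",
    "write_stack_tiff",
    "read_stack_tiff",
    "write_json",
    "read_json",
]


def write_reads_tsv(df: pd.DataFrame, path, total_mapped: int | None = None) -> None:
    with open(path, "w") as fh:
        if total_mapped is not None:
            fh.write(f"# total_mapped={total_mapped}\n")
        df.to_csv(fh, sep="\t", index=False)


def read_reads_tsv(path) -> tuple[pd.DataFrame, int | None]:
    """Read an aligned-read table; returns (frame, total_mapped or None)."""
    total_mapped = None
    with open(path) as fh:
        first = fh.readline()
        if first.startswith("# total_mapped="):
            total_mapped = int(first.strip().split("=", 1)[1])
            df = pd.read_csv(fh, sep="\t")
        else:
            fh.seek(0)
            df = pd.read_csv(fh, sep="\t")
    missing = [c for c in READ_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing read-table columns {missing}")
    for i, (s, e) in enumerate(zip(df["start"], df["end"]), start=2):
        if s < 0 or e <= s:
            raise ValueError(f"{path}: line {i}: bad interval [{s}, {e})")
    return df[READ_COLUMNS], total_mapped


def write_sites_bed(sites: list[BindingSite], path) -> None:
    with open(path, "w") as fh:
        for i, s in enumerate(sites):
            fh.write(
                f"{s.chrom}\t{s.start}\t{s.end}\tsite{i}\t0\t{s.strand}"
                f"\t{s.rpm:.10g}\t{s.n_conversion_reads}\n"
            )


def read_sites_bed(path, dataset_id: str = "") -> list[BindingSite]:
    sites = []
    with open(path) as fh:
        for i, line in enumerate(fh, start=1):
            fields = line.rstrip("\n").split("\t")
            if len(fields) != 8:
                raise ValueError(f"{path}: line {i}: expected 8 fields, got {len(fields)}")
            chrom, start, end, _name, _score, strand, rpm, nconv = fields
            try:
                sites.append(
                    BindingSite(
                        chrom=chrom,
                        strand=strand,
                        start=int(start),
                        end=int(end),
                        rpm=float(rpm),
                        n_conversion_reads=int(nconv),
                        dataset_id=dataset_id,
                    )
                )
            except ValueError as exc:
                raise ValueError(f"{path}: line {i}: {exc}") from exc
    return sites


def write_gene_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=True, index_label="gene_id")


def read_gene_table(path, require_integer: bool = False) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    if "gene_id" not in df.columns:
        raise ValueError(f"{path}: missing 'gene_id' column")
    df = df.set_index("gene_id")
    for col in df.columns:
        for i, v in enumerate(df[col], start=2):
            if v < 0:
                raise ValueError(f"{path}: line {i}: field {col}: negative value {v}")
            if require_integer and float(v) != int(v):
                raise ValueError(f"{path}: line {i}: field {col}: non-integer count {v}")
    return df


def write_cq_table(records: list[CqRecord], path) -> None:
    pd.DataFrame(
        [
            (r.probe_id, r.cq_eluate, r.cq_flow_through, r.ft_fraction)
            for r in records
        ],
        columns=["probe_id", "cq_eluate", "cq_flow_through", "ft_fraction"],
    ).to_csv(path, sep="\t", index=False)


def read_cq_table(path) -> list[CqRecord]:
    df = pd.read_csv(path, sep="\t")
    needed = {"probe_id", "cq_eluate", "cq_flow_through"}
    if not needed <= set(df.columns):
        raise ValueError(f"{path}: missing columns {sorted(needed - set(df.columns))}")
    out = []
    for i, row in df.iterrows():
        try:
            out.append(
                CqRecord(
                    probe_id=str(row["probe_id"]),
                    cq_eluate=float(row["cq_eluate"]),
                    cq_flow_through=float(row["cq_flow_through"]),
                    ft_fraction=float(row.get("ft_fraction", 0.25)),
                )
            )
        except ValueError as exc:
            raise ValueError(f"{path}: line {i + 2}: {exc}") from exc
    return out


def write_trace_tsv(trace: FrapTrace, path) -> None:
    cols = {"time_min": trace.times, "intensity": trace.intensity}
    for k in range(trace.controls.shape[0]):
        cols[f"control_{k + 1}"] = trace.controls[k]
    df = pd.DataFrame(cols)
    with open(path, "w") as fh:
        fh.write(
            f"# background={trace.background:.10g}\tbleach_index={trace.bleach_index}\n"
        )
        df.to_csv(fh, sep="\t", index=False)


def read_trace_tsv(path) -> FrapTrace:
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("#"):
            raise ValueError(f"{path}: line 1: missing '# background=...' header")
        meta = dict(
            item.split("=", 1) for item in header.lstrip("# ").strip().split("\t")
        )
        df = pd.read_csv(fh, sep="\t")
    ctrl_cols = [c for c in df.columns if c.startswith("control_")]
    if len(ctrl_cols) < 1:
        raise ValueError(f"{path}: no control_* columns")
    return FrapTrace(
        times=df["time_min"].to_numpy(),
        intensity=df["intensity"].to_numpy(),
        controls=df[ctrl_cols].to_numpy().T,
        background=float(meta["background"]),
        bleach_index=int(meta["bleach_index"]),
    )


def write_stack_tiff(stack: np.ndarray, path, pixel_size: float | None = None) -> None:
    desc = json.dumps({"pixel_size_um": pixel_size}) if pixel_size else None
    tifffile.imwrite(
        path,
        np.asarray(stack, dtype=np.float32),
        description=desc,
        photometric="minisblack",
    )


def read_stack_tiff(path) -> tuple[np.ndarray, float | None]:
    """Returns (stack, pixel_size_um or None).  A missing pixel size is
    not an error here; µm-dependent operations must check it themselves."""
    with tifffile.TiffFile(path) as tif:
        stack = tif.asarray()
        desc = tif.pages[0].description
    pixel_size = None
    if desc:
        try:
            pixel_size = json.loads(desc).get("pixel_size_um")
        except (json.JSONDecodeError, AttributeError):
            pixel_size = None
    return np.asarray(stack, dtype=float), pixel_size


def write_json(obj, path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


def read_json(path):
    return json.loads(Path(path).read_text())
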