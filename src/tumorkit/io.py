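"""Shared I/O: schema-checked tables, SIF, masks, gating trees, and minimal
VCF/SAM readers.

All tabular interchange is plain TSV/CSV with documented headers; binary
rasters travel as single-channel PNG/TIFF with a JSON sidecar carrying the
pixel size. The VCF and SAM readers are deliberately minimal: they extract
only the fields the downstream analyses consume (GT/AD/DP genotype fields;
UMI-tagged read sequences).
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .spatial import ECMMask, GateNode, parse_gating_tree

__all__ = [
    "SchemaError",
    "read_table",
    "write_table",
    "read_sif",
    "write_sif",
    "read_mask",
    "write_mask",
    "read_gating_tree",
    "read_vcf_variants",
    "read_sam_families",
]


class SchemaError(ValueError):
    """A table does not match its expected schema."""


def read_table(
    path: str | Path,
    required_columns: Sequence[str] | None = None,
    sep: str = "\t",
) -> pd.DataFrame:
    """Read a delimited table, checking the header against a schema.

    Raises :class:`SchemaError` naming any missing columns; malformed rows
    surface with pandas' line-numbered tokenizer errors.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, sep=sep)
    except pd.errors.EmptyDataError as exc:
        raise SchemaError(f"{path}: file is empty") from exc
    except pd.errors.ParserError as exc:
        raise SchemaError(f"{path}: {exc}") from exc
    if required_columns:
        missing = [c for c in required_columns if c not in df.columns]
        if missing:
            raise SchemaError(f"{path}: missing required columns {missing}")
    return df


def write_table(df: pd.DataFrame, path: str | Path, sep: str = "\t", index: bool = False) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep=sep, index=index)


def read_sif(path: str | Path) -> pd.DataFrame:
    """Read a SIF interaction file (3 columns, optional 4th sign column)."""
    from .regulon import parse_sif

    with open(path) as fh:
        return parse_sif(fh)


def write_sif(edges: pd.DataFrame, path: str | Path) -> None:
    """Write (regulator, relation, target[, sign]) rows as SIF text."""
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        for row in edges.itertuples(index=False):
            fh.write("\t".join(str(x) for x in row) + "\n")


def write_mask(mask: ECMMask, path: str | Path) -> None:
    """Write a binary mask as 8-bit PNG/TIFF plus a JSON pixel-size sidecar."""
    from PIL import Image

    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    img = Image.fromarray((mask.data.astype(np.uint8)) * 255)
    img.save(path)
    sidecar = path.with_suffix(path.suffix + ".json")
    sidecar.write_text(json.dumps({"pixel_size_um": mask.pixel_size}))


def read_mask(path: str | Path) -> ECMMask:
    """Read a binary mask raster and its pixel-size sidecar."""
    from PIL import Image

    path = Path(path)
    sidecar = path.with_suffix(path.suffix + ".json")
    if not sidecar.exists():
        raise FileNotFoundError(f"mask sidecar with pixel size not found: {sidecar}")
    meta = json.loads(sidecar.read_text())
    data = np.asarray(Image.open(path)) > 0
    return ECMMask(data=data, pixel_size=float(meta["pixel_size_um"]))


def read_gating_tree(path: str | Path) -> "GateNode | str":
    """Load a hierarchical gating tree from a YAML config."""
    with open(path) as fh:
        spec = yaml.safe_load(fh)
    return parse_gating_tree(spec)


def read_vcf_variants(path: str | Path) -> pd.DataFrame:
    """Minimal VCF reader producing per-sample variant observations.

    Uses only GT (called = any non-reference allele), AD (supporting
    reads = first alternate depth) and DP. Returns the standard variant
    observation table (sample_id, variant_id, vaf, depth, called,
    supporting_reads).
    """
    from cyvcf2 import VCF

    rows = []
    vcf = VCF(str(path))
    samples = vcf.samples
    for var in vcf:
        vid = f"{var.CHROM}:{var.POS}{var.REF}>{var.ALT[0] if var.ALT else '.'}"
        depths = var.format("DP")
        ads = var.format("AD")
        gts = var.gt_types  # 0=hom-ref, 1=het, 2=unknown, 3=hom-alt
        for i, sample in enumerate(samples):
            depth = int(depths[i][0]) if depths is not None else 0
            alt = int(ads[i][1]) if ads is not None and ads.shape[1] > 1 else 0
            called = gts[i] in (1, 3)
            vaf = alt / depth if depth > 0 else 0.0
            rows.append(
                {
                    "sample_id": sample,
                    "variant_id": vid,
                    "vaf": vaf,
                    "depth": depth,
                    "called": called,
                    "supporting_reads": alt,
                }
            )
    return pd.DataFrame(rows)


def read_sam_families(path: str | Path, umi_tag: str = "RX"):
    """Minimal SAM reader grouping UMI-tagged reads into families.

    Each mapped record contributes (umi, site_window, sequence) with the
    window keyed by reference name; records lacking the UMI tag are
    skipped. Returns the grouped read families.
    """
    import pysam

    from .ctdna import group_reads

    records = []
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as fh:
        for aln in fh:
            if aln.is_unmapped or aln.query_sequence is None:
                continue
            try:
                umi = aln.get_tag(umi_tag)
            except KeyError:
                continue
            records.append((str(umi), str(aln.reference_name), aln.query_sequence))
    return group_reads(records)
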