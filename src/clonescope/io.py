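"""Format round-trips: VCF, BED, Newick, TSV, JSON, YAML.

Coordinates are 0-based half-open internally; VCF is 1-based and the
conversion happens exactly here, at the format boundary.  Parsing uses
pysam (VCF) and dendropy (Newick); writers emit minimal, valid files so
parse -> write is semantically idempotent at the field level.
"""

from __future__ import annotations

import json
from pathlib import Path

import dendropy
import pandas as pd
import pysam
import yaml

__all__ = [
    "write_vcf", "read_vcf",
    "write_bed", "read_bed",
    "write_newick", "read_newick",
    "write_tsv", "read_tsv",
    "write_json", "read_json",
    "write_yaml", "read_yaml",
    "roundtrip_io",
]

_VCF_HEADER = """##fileformat=VCFv4.2
{info_lines}{contig_lines}#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO
"""

_INFO_TYPES = {int: "Integer", float: "Float", str: "String", bool: "Flag"}


def write_vcf(variants: pd.DataFrame, path, info_fields=()) -> None:
    """Write a minimal VCF 4.2.

    ``variants`` has columns chrom, pos (0-based; written as pos+1), ref,
    alt and optionally ``id`` plus any columns named in ``info_fields``
    (typed from the first non-null value).
    """
    df = variants.copy()
    info_lines = []
    for f in info_fields:
        if pd.api.types.is_bool_dtype(df[f]):
            ftype = "Flag"
        elif pd.api.types.is_integer_dtype(df[f]):
            ftype = "Integer"
        elif pd.api.types.is_float_dtype(df[f]):
            ftype = "Float"
        else:
            ftype = "String"
        num = "0" if ftype == "Flag" else "1"
        info_lines.append(f'##INFO=<ID={f},Number={num},Type={ftype},'
                          f'Description="{f}">\n')
    contigs = sorted(df["chrom"].astype(str).unique())
    contig_lines = "".join(f"##contig=<ID={c}>\n" for c in contigs)
    with open(path, "w") as fh:
        fh.write(_VCF_HEADER.format(info_lines="".join(info_lines),
                                    contig_lines=contig_lines))
        for r in df.itertuples(index=False):
            parts = []
            for f in info_fields:
                v = getattr(r, f)
                if isinstance(v, bool):
                    if v:
                        parts.append(f)
                elif pd.notna(v):
                    parts.append(f"{f}={v}")
            info = ";".join(parts) or "."
            vid = getattr(r, "id", ".") if "id" in df.columns else "."
            fh.write(f"{r.chrom}\t{int(r.pos) + 1}\t{vid}\t{r.ref}\t{r.alt}"
                     f"\t.\t.\t{info}\n")


def read_vcf(path) -> pd.DataFrame:
    """Read a VCF into a DataFrame with 0-based positions and INFO columns."""
    rows = []
    try:
        vf = pysam.VariantFile(str(path))
    except (ValueError, OSError) as exc:
        raise ValueError(f"cannot parse VCF {path}: {exc}") from exc
    for rec in vf:
        row = {"chrom": rec.chrom, "pos": rec.pos - 1, "id": rec.id or ".",
               "ref": rec.ref, "alt": rec.alts[0] if rec.alts else "."}
        for k, v in rec.info.items():
            if isinstance(v, tuple) and len(v) == 1:
                v = v[0]
            row[k] = v
        rows.append(row)
    vf.close()
    return pd.DataFrame(rows)


def write_bed(intervals: pd.DataFrame, path) -> None:
    """BED3(+name): 0-based half-open chrom/start/end (+ optional name)."""
    cols = ["chrom", "start", "end"] + (["name"] if "name" in intervals else [])
    intervals[cols].to_csv(path, sep="\t", header=False, index=False)


def read_bed(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    names = ["chrom", "start", "end", "name"][: df.shape[1]]
    df.columns = names + list(df.columns[len(names):])
    return df


def write_newick(tree: dendropy.Tree, path) -> None:
    tree.write(path=str(path), schema="newick", suppress_rooting=True,
               suppress_annotations=True, unquoted_underscores=True)


def read_newick(path) -> dendropy.Tree:
    return dendropy.Tree.get(path=str(path), schema="newick",
                             preserve_underscores=True)


def write_tsv(df: pd.DataFrame, path, index: bool = False) -> None:
    df.to_csv(path, sep="\t", index=index)


def read_tsv(path, **kwargs) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", **kwargs)


def write_json(obj, path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, default=_json_default)
        fh.write("\n")


def _json_default(o):
    try:
        import numpy as np
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
    except ImportError:  # pragma: no cover
        pass
    raise TypeError(f"not JSON serializable: {type(o)}")


def read_json(path):
    with open(path) as fh:
        return json.load(fh)


def write_yaml(obj, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(obj, fh, sort_keys=True)


def read_yaml(path):
    with open(path) as fh:
        return yaml.safe_load(fh)


_READERS = {"VCF": read_vcf, "BED": read_bed, "Newick": read_newick,
            "TSV": read_tsv, "JSON": read_json, "YAML": read_yaml}
_WRITERS = {"VCF": None, "BED": write_bed, "Newick": write_newick,
            "TSV": write_tsv, "JSON": write_json, "YAML": write_yaml}


def roundtrip_io(path, fmt: str, out_path=None):
    """Parse a file and rewrite it; returns (parsed object, rewritten path).

    Supported formats: VCF, BED, Newick, TSV, JSON, YAML.  The rewrite is
    semantically idempotent at the field level (column order and float
    formatting may differ).
    """
    if fmt not in _READERS:
        raise ValueError(f"unsupported format {fmt!r}")
    obj = _READERS[fmt](path)
    if out_path is None:
        p = Path(path)
        out_path = p.with_name(p.stem + ".roundtrip" + p.suffix)
    if fmt == "VCF":
        info = [c for c in obj.columns
                if c not in ("chrom", "pos", "id", "ref", "alt")]
        write_vcf(obj, out_path, info_fields=info)
    else:
        _WRITERS[fmt](obj, out_path)
    return obj, out_path
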