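"""File-format plumbing: images, ENVI cubes, GFF3, trait CSVs, manifests."""

from __future__ import annotations

from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile


def write_png_stack(stack: np.ndarray, directory, prefix: str = "view") -> list:
    """Write an (n_views, H, W, 3) RGB stack as numbered PNGs."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = []
    for i, view in enumerate(stack):
        p = directory / f"{prefix}_{i:03d}.png"
        iio.imwrite(p, np.asarray(view, dtype=np.uint8))
        paths.append(p)
    return paths


def read_png_stack(directory, prefix: str = "view") -> np.ndarray:
    paths = sorted(Path(directory).glob(f"{prefix}_*.png"))
    return np.stack([iio.imread(p) for p in paths])


def write_tiff(array: np.ndarray, path) -> None:
    tifffile.imwrite(path, np.asarray(array, dtype=np.float32))


def read_tiff(path) -> np.ndarray:
    return tifffile.imread(path)


def write_cube_tiff(cube: np.ndarray, path) -> None:
    """HSI cube as a multi-page TIFF, one page per band."""
    tifffile.imwrite(path, np.asarray(cube, dtype=np.float32),
                     photometric="minisblack")


def write_envi(cube: np.ndarray, path_stem) -> tuple:
    """ENVI-style raw cube (BSQ float32) plus text header."""
    stem = Path(path_stem)
    raw, hdr = stem.with_suffix(".raw"), stem.with_suffix(".hdr")
    data = np.asarray(cube, dtype="<f4")
    bands, lines, samples = data.shape
    data.tofile(raw)
    hdr.write_text(
        "ENVI\n"
        f"samples = {samples}\nlines = {lines}\nbands = {bands}\n"
        "header offset = 0\nfile type = ENVI Standard\n"
        "data type = 4\ninterleave = bsq\nbyte order = 0\n")
    return raw, hdr


def read_envi(path_stem) -> np.ndarray:
    stem = Path(path_stem)
    hdr = {}
    for line in stem.with_suffix(".hdr").read_text().splitlines():
        if "=" in line:
            k, v = line.split("=", 1)
            hdr[k.strip()] = v.strip()
    shape = tuple(int(hdr[k]) for k in ("bands", "lines", "samples"))
    return np.fromfile(stem.with_suffix(".raw"), dtype="<f4").reshape(shape)


GFF3_COLUMNS = ["seqid", "source", "type", "start", "end", "score",
                "strand", "phase", "attributes"]


def write_gff3(annotations: pd.DataFrame, path) -> None:
    """Write gene annotations (gene_id, chrom, start, end, strand) as GFF3."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for _, g in annotations.iterrows():
            fh.write(f"{g.chrom}\titrait\tgene\t{g.start}\t{g.end}\t.\t"
                     f"{g.strand}\t.\tID={g.gene_id}\n")


def read_gff3(path, feature_type: str = "gene") -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#", header=None,
                     names=GFF3_COLUMNS)
    df = df[df.type == feature_type]
    gene_id = df.attributes.str.extract(r"ID=([^;]+)")[0]
    return pd.DataFrame({"gene_id": gene_id, "chrom": df.seqid,
                         "start": df.start.astype(int),
                         "end": df.end.astype(int),
                         "strand": df.strand}).reset_index(drop=True)


def write_trait_csv(records: pd.DataFrame, path) -> None:
    cols = ["accession", "treatment", "day", "trait_id", "value"]
    df = records.rename(columns={"trait": "trait_id"})
    df[[c for c in cols if c in df.columns]].to_csv(path, index=False)


def write_manifest(entries: dict, path) -> None:
    """Plain-text key=value manifest recording seeds and ground truth."""
    with open(path, "w") as fh:
        for key, value in entries.items():
            fh.write(f"{key}={value}\n")


def read_manifest(path) -> dict:
    out = {}
    for line in Path(path).read_text().splitlines():
        if "=" in line:
            k, v = line.split("=", 1)
            out[k] = v
    return out
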