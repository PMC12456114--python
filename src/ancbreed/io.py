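"""File formats: panel TSVs, trajectory tables, matrix and VCF ingestion.

A panel is serialized as one TSV per track (G, A, F): rows are haplotypes
labelled ``i{index}_h{1|2}`` (individuals 1-based), columns are SNPs with a
header row of map positions in Morgans.  Comment lines (``#``) at the top
carry the tool version, the resolved seed, a config hash, the generation
index and the genetic length, so every output is reproducible from
``(config, seed)`` alone and round-trips bit-exactly.

The real-data entry points accept either a pair of haplotype matrices
(genotypes + binary local-ancestry calls) in the same TSV layout, or a
phased biallelic VCF with the ancestry sidecar; every input haplotype is
treated as a founder haplotype and given a fresh unique founder label.
"""

from __future__ import annotations

import os
import tempfile

import numpy as np
import pandas as pd

from . import __version__
from .genome import GenomeMap, Panel, founder_labels

__all__ = [
    "write_panel",
    "read_panel",
    "write_trajectory",
    "read_haplotype_ancestry_matrices",
    "read_phased_vcf",
]

_TRACKS = ("G", "A", "F")


def _meta_lines(seed=None, cfg_hash=None, **extra) -> list[str]:
    parts = [f"ancbreed v{__version__}"]
    if seed is not None:
        parts.append(f"seed={seed}")
    if cfg_hash is not None:
        parts.append(f"config={cfg_hash}")
    lines = ["# " + " ".join(parts)]
    for k, v in extra.items():
        lines.append(f"# {k}={v!r}")
    return lines


def _atomic_write(path: str, text: str) -> None:
    d = os.path.dirname(os.path.abspath(path))
    fd, tmp = tempfile.mkstemp(dir=d, suffix=".tmp")
    try:
        with os.fdopen(fd, "w") as fh:
            fh.write(text)
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise


def _hap_index(n: int) -> list[str]:
    return [f"i{i}_h{h}" for i in range(1, n + 1) for h in (1, 2)]


def write_panel(
    panel: Panel,
    prefix: str,
    genome_map: GenomeMap,
    seed=None,
    cfg_hash=None,
) -> list[str]:
    """Write ``<prefix>.G.tsv``, ``.A.tsv`` and ``.F.tsv``; return the paths."""
    header = "\t".join(["haplotype"] + [repr(float(p)) for p in genome_map.positions])
    paths = []
    for track in _TRACKS:
        arr = getattr(panel, track).reshape(2 * panel.N, panel.L)
        lines = _meta_lines(
            seed=seed, cfg_hash=cfg_hash, generation=panel.t, D=genome_map.D
        )
        lines.append(header)
        for row_label, row in zip(_hap_index(panel.N), arr):
            lines.append(row_label + "\t" + "\t".join(str(int(x)) for x in row))
        path = f"{prefix}.{track}.tsv"
        _atomic_write(path, "\n".join(lines) + "\n")
        paths.append(path)
    return paths


def _read_matrix(path: str) -> tuple[np.ndarray, np.ndarray, dict]:
    """Read one haplotype-matrix TSV -> (values, positions, metadata)."""
    meta: dict = {}
    with open(path) as fh:
        header = None
        rows, labels = [], []
        for ln, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line:
                continue
            if line.startswith("#"):
                body = line[1:].strip()
                if "=" in body and " " not in body.split("=", 1)[0]:
                    k, v = body.split("=", 1)
                    meta[k] = v
                continue
            parts = line.split("\t")
            if header is None:
                header = parts
                continue
            labels.append(parts[0])
            rows.append(parts[1:])
    if header is None or not rows:
        raise ValueError(f"{path}: no data rows found")
    try:
        positions = np.array([float(x) for x in header[1:]])
    except ValueError as e:
        raise ValueError(f"{path}: header positions must be numeric ({e})") from None
    if np.any(np.diff(positions) <= 0):
        bad = int(np.flatnonzero(np.diff(positions) <= 0)[0]) + 2
        raise ValueError(f"{path}: positions not strictly increasing at column {bad}")
    width = len(positions)
    vals = np.empty((len(rows), width), dtype=np.int64)
    for r, (lab, row) in enumerate(zip(labels, rows)):
        if len(row) != width:
            raise ValueError(
                f"{path}: row {lab!r} has {len(row)} values, expected {width}"
            )
        try:
            vals[r] = [int(x) for x in row]
        except ValueError:
            raise ValueError(f"{path}: non-integer value in row {lab!r}") from None
    if len(labels) % 2:
        raise ValueError(f"{path}: odd number of haplotype rows ({len(labels)})")
    meta["_labels"] = labels
    return vals, positions, meta


def read_panel(prefix: str) -> tuple[Panel, GenomeMap]:
    """Read a panel written by :func:`write_panel`."""
    tracks, positions, meta = {}, None, {}
    for track in _TRACKS:
        vals, pos, m = _read_matrix(f"{prefix}.{track}.tsv")
        tracks[track] = vals
        if positions is not None and not np.array_equal(pos, positions):
            raise ValueError(f"{prefix}: track position headers disagree")
        positions = pos
        meta.update(m)
    n_hap, L = tracks["G"].shape
    shape = (n_hap // 2, 2, L)
    D = float(meta.get("D", positions[-1]))
    t = int(meta.get("generation", 0))
    gm = GenomeMap(L, D, positions=positions)
    panel = Panel(
        t=t,
        G=tracks["G"].reshape(shape),
        A=tracks["A"].reshape(shape),
        F=tracks["F"].reshape(shape),
    )
    return panel, gm


def write_trajectory(df: pd.DataFrame, path: str, seed=None, cfg_hash=None) -> None:
    """Write a score-trajectory table with the standard metadata header."""
    lines = _meta_lines(seed=seed, cfg_hash=cfg_hash)
    lines.append(df.to_csv(sep="\t", index=False).rstrip("\n"))
    _atomic_write(path, "\n".join(lines) + "\n")


def read_trajectory(path: str) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")


def _panel_from_hap_matrices(
    geno: np.ndarray, anc: np.ndarray, positions: np.ndarray, D: float | None
) -> tuple[Panel, GenomeMap]:
    n_hap, L = geno.shape
    n = n_hap // 2
    for name, arr in (("genotype", geno), ("ancestry", anc)):
        bad = (arr != 0) & (arr != 1)
        if bad.any():
            r, c = map(int, np.argwhere(bad)[0])
            raise ValueError(
                f"non-binary {name} value {arr[r, c]} at haplotype row {r + 1}, SNP {c + 1}"
            )
    F = np.repeat(founder_labels(n)[:, :, None], L, axis=2)
    panel = Panel(
        t=0,
        G=geno.reshape(n, 2, L),
        A=anc.reshape(n, 2, L),
        F=F,
    )
    gm = GenomeMap(L, float(D) if D is not None else float(positions[-1]), positions=positions)
    return panel, gm


def read_haplotype_ancestry_matrices(
    path_genotypes: str, path_ancestry: str
) -> tuple[Panel, GenomeMap]:
    """Build a program panel from genotype + local-ancestry haplotype TSVs.

    The two files must have identical shapes and position headers.  Every
    input haplotype is treated as a founder haplotype: founder labels are
    initialized fresh, so individual i carries labels (2i-1, 2i).
    """
    geno, pos_g, meta = _read_matrix(path_genotypes)
    anc, pos_a, _ = _read_matrix(path_ancestry)
    if geno.shape != anc.shape:
        raise ValueError(
            f"shape mismatch: genotypes {geno.shape} vs ancestry {anc.shape}"
        )
    if not np.array_equal(pos_g, pos_a):
        raise ValueError("genotype and ancestry position headers disagree")
    return _panel_from_hap_matrices(geno, anc, pos_g, meta.get("D"))


def read_phased_vcf(path_vcf: str, path_ancestry: str) -> tuple[Panel, GenomeMap]:
    """Build a program panel from a phased biallelic VCF + ancestry sidecar.

    All genotypes must be phased ("0|1" style) with no missing calls, and
    all sites biallelic SNVs; violations are rejected naming the offending
    site.  Positions in Morgans are taken from the ancestry sidecar header,
    which must list the same number of sites in order.
    """
    from cyvcf2 import VCF

    anc, positions, meta = _read_matrix(path_ancestry)
    vcf = VCF(path_vcf)
    haps: list[np.ndarray] = []
    for var in vcf:
        site = f"{var.CHROM}:{var.POS}"
        if len(var.ALT) != 1:
            raise ValueError(f"multiallelic site at {site}")
        gts = np.asarray(var.genotypes)
        if np.any(gts[:, :2] < 0):
            raise ValueError(f"missing genotype at {site}")
        if np.any(gts[:, 2] == 0):
            raise ValueError(f"unphased genotype at {site}")
        if np.any(gts[:, :2] > 1):
            raise ValueError(f"non-biallelic allele index at {site}")
        haps.append(gts[:, :2].reshape(-1))
    vcf.close()
    if not haps:
        raise ValueError(f"{path_vcf}: no variant records")
    geno = np.stack(haps, axis=1)  # (2N, L)
    if geno.shape != anc.shape:
        raise ValueError(
            f"shape mismatch: VCF haplotypes {geno.shape} vs ancestry {anc.shape}"
        )
    return _panel_from_hap_matrices(geno, anc, positions, meta.get("D"))
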