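"""Readers and writers for the external formats the pipeline touches.

All genomic intervals are 0-based half-open throughout the package. Tables
are plain TSV; motifs use the MEME minimal format; peaks use ENCODE
narrowPeak (BED6+4); promoter sequences are FASTA with record id = gene_id;
gene sets use GMT. Every reader validates and raises :class:`FormatError`
naming the offending line or field.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord


class FormatError(ValueError):
    """Raised when an input file violates its format contract."""


VALID_STRANDS = {"+", "-"}
VALID_CONDITIONS = {"UW", "W"}

ANNOTATION_COLUMNS = [
    "gene_id", "chrom", "strand", "tss", "length_nt", "is_tf",
    "is_chromatin_factor",
]


# ---------------------------------------------------------------------------
# gene annotation


def read_annotation(path) -> pd.DataFrame:
    """Read a gene annotation TSV into a DataFrame indexed by gene_id.

    Columns: chrom, strand (+/-), tss (0-based), length_nt, is_tf,
    is_chromatin_factor. Duplicated gene ids, negative TSS, non-positive
    lengths and unknown strands are rejected.
    """
    df = pd.read_csv(path, sep="\t", dtype={"gene_id": str, "chrom": str, "strand": str})
    missing = [c for c in ANNOTATION_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"annotation {path}: missing column(s) {missing}")
    dup = df["gene_id"][df["gene_id"].duplicated()]
    if len(dup):
        raise FormatError(f"annotation {path}: duplicate gene_id {dup.iloc[0]!r}")
    bad_strand = ~df["strand"].isin(VALID_STRANDS)
    if bad_strand.any():
        i = int(np.flatnonzero(bad_strand)[0])
        raise FormatError(
            f"annotation {path}: line {i + 2}: strand {df['strand'].iloc[i]!r} "
            "not in {+,-}")
    if (df["tss"] < 0).any():
        i = int(np.flatnonzero(df["tss"] < 0)[0])
        raise FormatError(f"annotation {path}: line {i + 2}: negative tss")
    if (df["length_nt"] < 1).any():
        i = int(np.flatnonzero(df["length_nt"] < 1)[0])
        raise FormatError(f"annotation {path}: line {i + 2}: length_nt < 1")
    df = df.set_index("gene_id")
    df["tss"] = df["tss"].astype(np.int64)
    df["length_nt"] = df["length_nt"].astype(np.int64)
    df["is_tf"] = df["is_tf"].astype(bool)
    df["is_chromatin_factor"] = df["is_chromatin_factor"].astype(bool)
    return df


def write_annotation(annotation: pd.DataFrame, path) -> None:
    annotation.reset_index().rename(columns={"index": "gene_id"}).to_csv(
        path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# counts + design


def read_counts_design(counts_path, design_path) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Read a gene x sample count TSV plus its sample design TSV.

    The returned count matrix has columns reordered to match the design's
    sample order; counts must be non-negative integers.
    """
    counts = pd.read_csv(counts_path, sep="\t", index_col=0)
    design = read_design(design_path)
    missing = [s for s in design["sample_id"] if s not in counts.columns]
    if missing:
        raise FormatError(
            f"design sample(s) {missing} absent from counts columns")
    counts = counts[list(design["sample_id"])]
    arr = counts.to_numpy()
    if not np.all(np.isfinite(arr)):
        raise FormatError("counts contain non-finite values")
    if np.any(arr < 0):
        raise FormatError("counts contain negative values")
    if not np.all(arr == np.floor(arr)):
        g, s = np.argwhere(arr != np.floor(arr))[0]
        raise FormatError(
            f"non-integer count {arr[g, s]} at gene {counts.index[g]!r}, "
            f"sample {counts.columns[s]!r}")
    counts = counts.astype(np.int64)
    counts.index = counts.index.astype(str)
    return counts, design


def read_design(path) -> pd.DataFrame:
    design = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "condition": str})
    for col in ("sample_id", "condition", "timepoint_h", "replicate"):
        if col not in design.columns:
            raise FormatError(f"design {path}: missing column {col!r}")
    if design["sample_id"].duplicated().any():
        raise FormatError(f"design {path}: duplicate sample_id")
    bad = ~design["condition"].isin(VALID_CONDITIONS)
    if bad.any():
        raise FormatError(
            f"design {path}: condition must be in {{UW,W}}, got "
            f"{design['condition'][bad].iloc[0]!r}")
    design["timepoint_h"] = design["timepoint_h"].astype(float)
    design["replicate"] = design["replicate"].astype(int)
    return design


def write_counts_design(counts: pd.DataFrame, design: pd.DataFrame,
                        counts_path, design_path) -> None:
    counts.to_csv(counts_path, sep="\t", index_label="gene_id")
    design.to_csv(design_path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# narrowPeak


def read_narrowpeak(path, tf_id: str) -> pd.DataFrame:
    """Parse an ENCODE narrowPeak (BED6+4) file, tagging peaks with tf_id.

    Returns a DataFrame with columns chrom, start, end, tf_id, score.
    Intervals are 0-based half-open as in BED.
    """
    rows = []
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("track", "#")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise FormatError(f"{path}: line {ln}: fewer than 3 fields")
            chrom = parts[0]
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError as exc:
                raise FormatError(
                    f"{path}: line {ln}: non-numeric coordinates") from exc
            if start >= end:
                raise FormatError(
                    f"{path}: line {ln}: start {start} >= end {end}")
            score = float(parts[4]) if len(parts) > 4 else np.nan
            rows.append((chrom, start, end, tf_id, score))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "tf_id", "score"])


def write_narrowpeak(peaks: pd.DataFrame, path) -> None:
    with open(path, "w") as fh:
        for i, row in enumerate(peaks.itertuples(index=False)):
            score = 0 if not np.isfinite(getattr(row, "score", np.nan)) else row.score
            fh.write(f"{row.chrom}\t{row.start}\t{row.end}\tpeak{i}\t{score}\t.\t"
                     "0\t-1\t-1\t-1\n")


# ---------------------------------------------------------------------------
# MEME motifs


@dataclass
class PWM:
    """A position weight matrix: L x 4 base probabilities over A,C,G,T."""

    motif_id: str
    tf_id: str
    probs: np.ndarray
    background: np.ndarray = field(
        default_factory=lambda: np.full(4, 0.25))

    def __post_init__(self):
        self.probs = np.asarray(self.probs, dtype=float)
        self.background = np.asarray(self.background, dtype=float)
        if self.probs.ndim != 2 or self.probs.shape[1] != 4:
            raise FormatError(f"PWM {self.motif_id}: probs must be L x 4")
        if self.probs.shape[0] < 4:
            raise FormatError(f"PWM {self.motif_id}: length must be >= 4")
        if np.any(np.abs(self.probs.sum(axis=1) - 1.0) > 1e-3):
            raise FormatError(
                f"PWM {self.motif_id}: probability row does not sum to 1")
        if abs(self.background.sum() - 1.0) > 1e-3:
            raise FormatError(f"PWM {self.motif_id}: background does not sum to 1")

    def __len__(self) -> int:
        return self.probs.shape[0]

    @property
    def consensus(self) -> str:
        return "".join("ACGT"[i] for i in self.probs.argmax(axis=1))


def read_meme_pwms(path, motif_to_tf: dict[str, str] | None = None) -> list[PWM]:
    """Read PWMs from a MEME minimal-format motif file.

    The TF id defaults to the motif's alternate name (second MOTIF token) or,
    failing that, the motif id; ``motif_to_tf`` overrides either.
    """
    pwms: list[PWM] = []
    background = np.full(4, 0.25)
    with open(path) as fh:
        lines = fh.read().splitlines()
    i = 0
    while i < len(lines):
        line = lines[i].strip()
        if line.lower().startswith("background letter frequencies"):
            toks = lines[i + 1].split()
            freqs = {toks[j]: float(toks[j + 1]) for j in range(0, len(toks), 2)}
            background = np.array([freqs.get(b, 0.25) for b in "ACGT"])
            i += 2
            continue
        if line.startswith("MOTIF"):
            toks = line.split()
            motif_id = toks[1]
            alt = toks[2] if len(toks) > 2 else motif_id
            # advance to the letter-probability matrix header
            j = i + 1
            while j < len(lines) and "letter-probability matrix" not in lines[j]:
                j += 1
            if j == len(lines):
                raise FormatError(
                    f"{path}: motif {motif_id}: no letter-probability matrix")
            rows = []
            j += 1
            while j < len(lines):
                stripped = lines[j].strip()
                if not stripped or stripped.startswith(("MOTIF", "URL")):
                    break
                rows.append([float(x) for x in stripped.split()])
                j += 1
            probs = np.asarray(rows)
            tf_id = (motif_to_tf or {}).get(motif_id, alt)
            pwms.append(PWM(motif_id, tf_id, probs, background))
            i = j
            continue
        i += 1
    return pwms


def write_meme_pwms(pwms: list[PWM], path) -> None:
    with open(path, "w") as fh:
        fh.write("MEME version 4\n\nALPHABET= ACGT\n\nstrands: + -\n\n")
        if pwms:
            bg = pwms[0].background
            fh.write("Background letter frequencies\n")
            fh.write(f"A {bg[0]:.5f} C {bg[1]:.5f} G {bg[2]:.5f} T {bg[3]:.5f}\n\n")
        for pwm in pwms:
            fh.write(f"MOTIF {pwm.motif_id} {pwm.tf_id}\n")
            fh.write(f"letter-probability matrix: alength= 4 w= {len(pwm)} "
                     f"nsites= 20 E= 0\n")
            for row in pwm.probs:
                fh.write(" ".join(f"{p:.6f}" for p in row) + "\n")
            fh.write("\n")


# ---------------------------------------------------------------------------
# GMT gene sets


@dataclass
class GeneSetCollection:
    """Named gene sets: set_id -> (description, member ids)."""

    sets: dict[str, tuple[str, frozenset[str]]]

    def __len__(self) -> int:
        return len(self.sets)

    def members(self, set_id: str) -> frozenset[str]:
        return self.sets[set_id][1]


def read_gmt(path) -> GeneSetCollection:
    sets: dict[str, tuple[str, frozenset[str]]] = {}
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise FormatError(f"{path}: line {ln}: set has no members")
            set_id, desc, members = parts[0], parts[1], [m for m in parts[2:] if m]
            if not members:
                raise FormatError(
                    f"{path}: line {ln}: set {set_id!r} has no members")
            if set_id in sets:
                raise FormatError(f"{path}: line {ln}: duplicate set_id {set_id!r}")
            sets[set_id] = (desc, frozenset(members))
    return GeneSetCollection(sets)


def write_gmt(collection: GeneSetCollection, path) -> None:
    with open(path, "w") as fh:
        for set_id, (desc, members) in collection.sets.items():
            fh.write("\t".join([set_id, desc] + sorted(members)) + "\n")


# ---------------------------------------------------------------------------
# FASTA promoters


def read_promoters(path) -> dict[str, str]:
    """Read promoter sequences keyed by gene_id from FASTA."""
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_promoters(promoters: dict[str, str], path) -> None:
    records = [SeqRecord(Seq(seq), id=gene, description="")
               for gene, seq in promoters.items()]
    SeqIO.write(records, str(path), "fasta")


# ---------------------------------------------------------------------------
# PPI and IDR plain TSVs


def read_ppi(path) -> pd.DataFrame:
    """Read an undirected PPI edge list TSV (protein_a, protein_b).

    Self-loops are rejected; duplicate edges (either orientation) are
    deduplicated.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    for col in ("protein_a", "protein_b"):
        if col not in df.columns:
            raise FormatError(f"PPI {path}: missing column {col!r}")
    if (df["protein_a"] == df["protein_b"]).any():
        raise FormatError(f"PPI {path}: self-loop present")
    lo = df[["protein_a", "protein_b"]].min(axis=1)
    hi = df[["protein_a", "protein_b"]].max(axis=1)
    out = pd.DataFrame({"protein_a": lo, "protein_b": hi}).drop_duplicates()
    return out.reset_index(drop=True)


def write_ppi(edges: pd.DataFrame, path) -> None:
    edges.to_csv(path, sep="\t", index=False)


def read_idr(path) -> pd.DataFrame:
    """Read IDR intervals TSV: protein_id, idr_start, idr_end, protein_length.

    Intervals are 0-based half-open within [0, protein_length).
    """
    df = pd.read_csv(path, sep="\t", dtype={"protein_id": str})
    for col in ("protein_id", "idr_start", "idr_end", "protein_length"):
        if col not in df.columns:
            raise FormatError(f"IDR {path}: missing column {col!r}")
    if ((df["idr_start"] < 0) | (df["idr_end"] > df["protein_length"])
            | (df["idr_start"] >= df["idr_end"])).any():
        raise FormatError(f"IDR {path}: interval outside [0, protein_length)")
    return df


def write_idr(idr: pd.DataFrame, path) -> None:
    idr.to_csv(path, sep="\t", index=False)


def idr_fractions(idr: pd.DataFrame) -> pd.Series:
    """Total merged IDR length / protein length per protein."""
    out = {}
    for pid, grp in idr.groupby("protein_id"):
        ivals = sorted(zip(grp["idr_start"], grp["idr_end"]))
        merged: list[list[int]] = []
        for s, e in ivals:
            if merged and s <= merged[-1][1]:
                merged[-1][1] = max(merged[-1][1], e)
            else:
                merged.append([s, e])
        total = sum(e - s for s, e in merged)
        out[pid] = total / float(grp["protein_length"].iloc[0])
    return pd.Series(out, name="idr_fraction")
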