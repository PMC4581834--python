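"""Readers and writers: ms/msms text, phased VCF windows, score tables.

The ms interchange format is the simulator-ecosystem text layout: replicates
separated by ``//`` lines, each with ``segsites: S``, ``positions:`` (window
fractions) and one 0/1 row per haplotype.  A JSON sidecar maps sample ids to
carrier/non-carrier ground truth.

VCF ingestion takes phased diploid genotypes in a window, polarizes each
site against an ancestral-allele source (explicit outgroup table takes
precedence over the VCF ``AA`` INFO tag) so that 1 marks the non-ancestral
allele, and drops — with logged counts — sites that are multi-allelic,
unphased, missing an ancestral call, or whose ancestral base matches
neither allele.
"""

from __future__ import annotations

import json
import logging
import os
from dataclasses import dataclass
from typing import Iterator, Mapping, Optional, TextIO

import numpy as np

from .core import HaplotypeMatrix, filter_polymorphic
from .precioss import CarrierPrediction, EvaluationResult, rank_percentile

logger = logging.getLogger("hafscore")

__all__ = [
    "WindowSpec",
    "read_ms",
    "write_ms",
    "read_truth_sidecar",
    "write_truth_sidecar",
    "read_vcf_window",
    "write_scores",
]


class MsParseError(ValueError):
    """Malformed ms-style text; message carries the offending line number."""


@dataclass
class WindowSpec:
    """1-based inclusive genomic window, or center ± flank."""

    chromosome: str
    start: int = None
    end: int = None

    def __post_init__(self):
        if self.start is None or self.end is None:
            raise ValueError("window needs start and end (or use from_center)")
        if self.start > self.end:
            raise ValueError(f"window start {self.start} > end {self.end}")

    @classmethod
    def from_center(cls, chromosome: str, center: int, width: int = 50_000) -> "WindowSpec":
        half = width // 2
        return cls(chromosome=chromosome, start=max(1, center - half), end=center + half)

    @property
    def length(self) -> int:
        return self.end - self.start + 1


# ----------------------------------------------------------------- ms format

def read_ms(
    path_or_handle, window_length: float = 1.0, truth: Optional[Mapping[str, str]] = None
) -> Iterator[HaplotypeMatrix]:
    """Parse ms/msms-style text into one HaplotypeMatrix per replicate.

    Positions (fractions of the window) are scaled by ``window_length`` bp.
    Matrices are returned as stored — call :func:`filter_polymorphic` before
    scoring if the source may contain fixed columns.
    """
    own = isinstance(path_or_handle, (str, bytes, os.PathLike))
    handle: TextIO = open(path_or_handle) if own else path_or_handle
    try:
        yield from _parse_ms(handle, window_length, truth)
    finally:
        if own:
            handle.close()


def _parse_ms(handle, window_length, truth):
    lines = handle.read().splitlines()
    i = 0
    while i < len(lines):
        if lines[i].strip() != "//":
            i += 1
            continue
        i += 1
        if i >= len(lines) or not lines[i].startswith("segsites:"):
            raise MsParseError(f"line {i + 1}: expected 'segsites:' after '//'")
        try:
            seg = int(lines[i].split(":", 1)[1])
        except ValueError as e:
            raise MsParseError(f"line {i + 1}: bad segsites value") from e
        i += 1
        positions = np.zeros(0)
        if seg > 0:
            if i >= len(lines) or not lines[i].startswith("positions:"):
                raise MsParseError(f"line {i + 1}: expected 'positions:'")
            fields = lines[i].split(":", 1)[1].split()
            if len(fields) != seg:
                raise MsParseError(
                    f"line {i + 1}: {len(fields)} positions for segsites {seg}"
                )
            positions = np.array([float(f) for f in fields]) * window_length
            i += 1
        rows = []
        while i < len(lines) and lines[i].strip() and lines[i].strip() != "//":
            row = lines[i].strip()
            if set(row) - {"0", "1"}:
                raise MsParseError(f"line {i + 1}: non-binary haplotype row")
            if len(row) != seg:
                raise MsParseError(
                    f"line {i + 1}: row length {len(row)} != segsites {seg}"
                )
            rows.append([int(ch) for ch in row])
            i += 1
        data = np.array(rows, dtype=np.int8) if rows else np.zeros((0, seg), np.int8)
        ids = [f"hap{j}" for j in range(len(rows))]
        ct = None
        if truth is not None:
            ct = np.array([truth.get(s) == "carrier" for s in ids])
        yield HaplotypeMatrix(
            data=data, positions=positions, sample_ids=ids, carrier_truth=ct
        )


def write_ms(matrices, path_or_handle, window_length: float = 1.0) -> None:
    """Write replicates in ms-style text (positions as window fractions)."""
    own = isinstance(path_or_handle, (str, bytes, os.PathLike))
    handle = open(path_or_handle, "w") if own else path_or_handle
    try:
        handle.write("hafscore ms output\n\n")
        for m in matrices:
            handle.write("//\n")
            handle.write(f"segsites: {m.num_sites}\n")
            if m.num_sites:
                frac = m.positions / window_length
                handle.write("positions: " + " ".join(f"{p:.8f}" for p in frac) + "\n")
            for row in m.data:
                handle.write("".join(str(int(x)) for x in row) + "\n")
            handle.write("\n")
    finally:
        if own:
            handle.close()


def write_truth_sidecar(matrix: HaplotypeMatrix, path) -> None:
    if matrix.carrier_truth is None:
        raise ValueError("matrix has no carrier_truth to write")
    payload = {
        s: ("carrier" if c else "non-carrier")
        for s, c in zip(matrix.sample_ids, matrix.carrier_truth)
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1)


def read_truth_sidecar(path) -> dict[str, str]:
    with open(path) as fh:
        return json.load(fh)


# --------------------------------------------------------------------- VCF

def read_vcf_window(
    path,
    window: WindowSpec,
    ancestral: Optional[Mapping[int, str]] = None,
    use_aa_tag: bool = True,
) -> HaplotypeMatrix:
    """Phased haplotypes in a window, polarized to ancestral (0) / derived (1).

    ``ancestral`` maps 1-based position -> ancestral base (an outgroup
    alignment table); it takes precedence over the VCF ``AA`` INFO tag.  With
    neither available for a site — or for multi-allelic, unphased, or
    ancestral-mismatch sites — the site is dropped and counted in the log.
    Returns one row per phased haplotype (two per diploid sample), already
    polymorphic-filtered.
    """
    from cyvcf2 import VCF

    if ancestral is None and not use_aa_tag:
        raise ValueError("no ancestral-allele source: supply a table or allow the AA tag")
    vcf = VCF(str(path))
    samples = vcf.samples
    sample_ids = [f"{s}_{h}" for s in samples for h in (1, 2)]
    nhap = len(sample_ids)
    cols, positions = [], []
    dropped = {"multiallelic": 0, "no_ancestral": 0, "mismatch": 0, "unphased": 0}
    region = f"{window.chromosome}:{window.start}-{window.end}"
    try:
        variants = iter(vcf(region))
        first = next(variants, None)
        variants = ([first] if first is not None else []) + list(variants)
    except Exception:
        # no tabix index (plain-text VCF): scan and filter
        variants = [
            v for v in vcf
            if v.CHROM == window.chromosome and window.start <= v.POS <= window.end
        ]
    for var in variants:
        if len(var.ALT) != 1 or len(var.REF) != 1 or len(var.ALT[0]) != 1:
            dropped["multiallelic"] += 1
            continue
        aa = None
        if ancestral is not None:
            aa = ancestral.get(var.POS)
        if aa is None and use_aa_tag:
            tag = var.INFO.get("AA")
            aa = tag.split("|")[0].upper() if tag else None
        if not aa or aa not in "ACGT":
            dropped["no_ancestral"] += 1
            continue
        if aa == var.REF:
            derived_is_alt = True
        elif aa == var.ALT[0]:
            derived_is_alt = False
        else:
            dropped["mismatch"] += 1
            continue
        gts = np.asarray(var.genotypes)          # (nsample, 3): a, b, phased
        if not np.all(gts[:, 2]) or (gts[:, :2] < 0).any():
            dropped["unphased"] += 1
            continue
        hap = gts[:, :2].reshape(-1).astype(np.int8)
        col = hap if derived_is_alt else (1 - hap).astype(np.int8)
        cols.append(col)
        positions.append(var.POS)
    vcf.close()
    total_dropped = sum(dropped.values())
    logger.info(
        "read_vcf_window %s: kept %d site(s), dropped %d (%s)",
        region, len(cols), total_dropped,
        ", ".join(f"{k}={v}" for k, v in dropped.items() if v),
    )
    if not cols and total_dropped == 0:
        raise ValueError(f"no phased biallelic sites found in window {region}")
    data = (
        np.stack(cols, axis=1) if cols else np.zeros((nhap, 0), dtype=np.int8)
    )
    matrix = HaplotypeMatrix(
        data=data, positions=np.asarray(positions, dtype=float), sample_ids=sample_ids
    )
    return filter_polymorphic(matrix)


# ------------------------------------------------------------- score output

def write_scores(
    prediction: CarrierPrediction,
    path,
    evaluation: Optional[EvaluationResult] = None,
    fmt: str = "tsv",
    sample_ids=None,
    seed: Optional[int] = None,
) -> None:
    """Per-haplotype score table (TSV) or its JSON mirror.

    Columns: sample_id, score, percentile, posterior_carrier, label.  The
    header records ℓ and the seed; an evaluation block (balanced accuracy,
    Wilcoxon p) is appended when truth-based evaluation is supplied.
    """
    n = len(prediction.scores)
    ids = list(sample_ids) if sample_ids is not None else [f"hap{i}" for i in range(n)]
    pct = rank_percentile(prediction.scores)
    hi = int(np.argmax(prediction.fit.means))
    post = prediction.fit.responsibilities[:, hi]
    if fmt == "tsv":
        with open(path, "w") as fh:
            fh.write(f"# ell={prediction.ell} seed={seed}\n")
            if evaluation is not None:
                fh.write(
                    f"# balanced_accuracy={evaluation.balanced_accuracy} "
                    f"wilcoxon_p={evaluation.wilcoxon_p}\n"
                )
            fh.write("sample_id\tscore\tpercentile\tposterior_carrier\tlabel\n")
            for i in range(n):
                lab = "carrier" if prediction.labels[i] else "non-carrier"
                fh.write(
                    f"{ids[i]}\t{int(prediction.scores[i])}\t{pct[i]:.4f}\t"
                    f"{post[i]:.6f}\t{lab}\n"
                )
    elif fmt == "json":
        payload = {
            "ell": prediction.ell,
            "seed": seed,
            "mixture": {
                "means": prediction.fit.means.tolist(),
                "variances": prediction.fit.variances.tolist(),
                "weights": prediction.fit.weights.tolist(),
                "loglik": prediction.fit.loglik,
                "low_confidence": bool(prediction.fit.low_confidence),
            },
            "haplotypes": [
                {
                    "sample_id": ids[i],
                    "score": int(prediction.scores[i]),
                    "percentile": float(pct[i]),
                    "posterior_carrier": float(post[i]),
                    "label": "carrier" if prediction.labels[i] else "non-carrier",
                }
                for i in range(n)
            ],
        }
        if evaluation is not None:
            payload["evaluation"] = {
                "tp": evaluation.tp, "fp": evaluation.fp,
                "tn": evaluation.tn, "fn": evaluation.fn,
                "balanced_accuracy": evaluation.balanced_accuracy,
                "wilcoxon_p": evaluation.wilcoxon_p,
            }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)
    else:
        raise ValueError(f"unknown format {fmt!r}: use 'tsv' or 'json'")
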