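"""File-format dialects: peak TSV, truth TSV, call-matrix TSV, manifests.

Peak tables mirror a fragment-analysis table export: tab-delimited, UTF-8,
``.`` for missing values.  Sized mode carries calibrated sizes
(``sample  dye  size  height``); raw mode carries migration units
(``sample  dye  raw  height``) with the ladder in a sidecar TSV
(``raw  size``).  Truth and call genotypes use VCF GT strings.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd

from .caller import Peak, PeakTable
from .synth import SampleTruth
from .panel import Panel

__all__ = [
    "IOError_",
    "RunConfig",
    "write_peaks_tsv",
    "read_peaks_tsv",
    "write_ladder_tsv",
    "read_ladder_tsv",
    "write_truth_tsv",
    "read_truth_tsv",
    "write_calls_tsv",
    "read_calls_tsv",
    "write_manifest",
]

MISSING = "."


class IOError_(ValueError):
    """Raised for malformed input files (message carries the line number)."""


@dataclass
class RunConfig:
    """One pipeline run's configuration (serialised into the manifest)."""

    panel: str = "hl32"
    seed: int = 0
    noise_seed: int | None = None
    strict_fixtures: bool = False
    min_height: float = 100.0
    out_dir: str = "."
    log_level: str = "INFO"
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.min_height <= 0:
            raise IOError_("min_height must be positive")


# ---------------------------------------------------------------------------
# Peak tables


def write_peaks_tsv(peak_tables: list[PeakTable], path, mode: str = "raw") -> None:
    """Write peak tables; ``mode`` is ``raw`` (migration units) or
    ``sized`` (requires peaks to carry sizes)."""
    if mode not in ("raw", "sized"):
        raise IOError_(f"unknown peaks mode {mode!r}")
    col = "raw" if mode == "raw" else "size"
    lines = [f"sample\tdye\t{col}\theight"]
    for tbl in peak_tables:
        for p in tbl.peaks:
            value = p.raw_units if mode == "raw" else p.size
            if value is None:
                raise IOError_(
                    f"{tbl.sample_id}: peak lacks {col}; cannot write {mode} mode"
                )
            lines.append(f"{tbl.sample_id}\t{p.dye}\t{value:.6g}\t{p.height:.6g}")
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def write_ladder_tsv(ladder: list[tuple[float, float]], path) -> None:
    lines = ["raw\tsize"] + [f"{m:.6g}\t{s:.6g}" for m, s in ladder]
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def read_ladder_tsv(path) -> list[tuple[float, float]]:
    ladder = []
    for ln, line in enumerate(Path(path).read_text(encoding="utf-8").splitlines(), 1):
        if ln == 1:
            if line.split("\t")[:2] != ["raw", "size"]:
                raise IOError_(f"{path}:1: expected header 'raw\\tsize'")
            continue
        if not line.strip():
            continue
        try:
            m, s = line.split("\t")[:2]
            ladder.append((float(m), float(s)))
        except ValueError as e:
            raise IOError_(f"{path}:{ln}: bad ladder line: {e}") from None
    return ladder


def read_peaks_tsv(path, ladder_path=None) -> list[PeakTable]:
    """Read a peak TSV (either dialect); raw mode needs the ladder sidecar."""
    text = Path(path).read_text(encoding="utf-8").splitlines()
    if not text:
        raise IOError_(f"{path}:1: empty peaks file")
    header = text[0].split("\t")
    if header == ["sample", "dye", "raw", "height"]:
        mode = "raw"
    elif header == ["sample", "dye", "size", "height"]:
        mode = "sized"
    else:
        raise IOError_(f"{path}:1: unrecognised peak header {header}")
    if mode == "raw" and ladder_path is None:
        raise IOError_(f"{path}: raw-mode peaks need a ladder sidecar")
    ladder = read_ladder_tsv(ladder_path) if ladder_path is not None else []

    tables: dict[str, PeakTable] = {}
    for ln, line in enumerate(text[1:], 2):
        if not line.strip():
            continue
        fields = line.split("\t")
        if len(fields) != 4:
            raise IOError_(f"{path}:{ln}: expected 4 fields, got {len(fields)}")
        sample, dye, value, height = fields
        try:
            h = float(height)
            val = None if value == MISSING else float(value)
        except ValueError as e:
            raise IOError_(f"{path}:{ln}: bad number: {e}") from None
        peak = (
            Peak(dye=dye, height=h, raw_units=val)
            if mode == "raw"
            else Peak(dye=dye, height=h, size=val)
        )
        if sample not in tables:
            tables[sample] = PeakTable(sample, [], list(ladder))
        tables[sample].peaks.append(peak)
    if not tables:
        raise IOError_(f"{path}: no peaks found")
    return list(tables.values())


# ---------------------------------------------------------------------------
# Truth sets


def write_truth_tsv(truths: list[SampleTruth], panel: Panel, path) -> None:
    """Truth TSV: one row per non-reference (sample, variant); variant-free
    samples keep one placeholder row so the sample list round-trips."""
    lines = ["sample\tvariant\tgt\tmt_fraction"]
    for t in truths:
        if not t.genotypes:
            lines.append(f"{t.sample_id}\t{MISSING}\t0/0\t{MISSING}")
            continue
        for name, g in t.genotypes.items():
            mt = panel.variant(name).is_mitochondrial
            gt = t.gt(name, mt)
            frac = f"{float(g):.4g}" if isinstance(g, float) else MISSING
            lines.append(f"{t.sample_id}\t{name}\t{gt}\t{frac}")
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


_GT_TO_ZYG = {"0/1": "het", "1/1": "hom_alt", "0/2": "het2", "2/2": "hom_alt2"}


def read_truth_tsv(path, panel: Panel) -> list[SampleTruth]:
    text = Path(path).read_text(encoding="utf-8").splitlines()
    if not text or text[0].split("\t")[:3] != ["sample", "variant", "gt"]:
        raise IOError_(f"{path}:1: expected truth header 'sample\\tvariant\\tgt...'")
    order: list[str] = []
    geno: dict[str, dict] = {}
    for ln, line in enumerate(text[1:], 2):
        if not line.strip():
            continue
        fields = line.split("\t")
        if len(fields) < 3:
            raise IOError_(f"{path}:{ln}: expected >= 3 fields")
        sample, variant, gt = fields[:3]
        frac = fields[3] if len(fields) > 3 else MISSING
        if sample not in geno:
            geno[sample] = {}
            order.append(sample)
        if variant == MISSING or gt == "0/0":
            continue
        try:
            v = panel.variant(variant)
        except KeyError:
            raise IOError_(f"{path}:{ln}: unknown variant {variant!r}") from None
        if v.is_mitochondrial:
            if frac != MISSING:
                geno[sample][variant] = float(frac)
            else:
                geno[sample][variant] = 1.0 if gt == "1/1" else 0.5
        else:
            if gt not in _GT_TO_ZYG:
                raise IOError_(f"{path}:{ln}: bad genotype {gt!r}")
            geno[sample][variant] = _GT_TO_ZYG[gt]
    return [SampleTruth(s, geno[s]) for s in order]


# ---------------------------------------------------------------------------
# Call matrices


def write_calls_tsv(calls: pd.DataFrame, path) -> None:
    calls.to_csv(path, sep="\t", index_label="sample")


def read_calls_tsv(path) -> pd.DataFrame:
    try:
        df = pd.read_csv(path, sep="\t", index_col="sample", dtype=str)
    except Exception as e:
        raise IOError_(f"{path}: cannot parse call matrix: {e}") from None
    return df


def write_manifest(path, config: RunConfig, inputs: dict, outputs: dict) -> None:
    from . import __version__

    doc = {
        "version": __version__,
        "config": asdict(config),
        "inputs": inputs,
        "outputs": outputs,
    }
    Path(path).write_text(
        json.dumps(doc, indent=1, sort_keys=True) + "\n", encoding="utf-8"
    )
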