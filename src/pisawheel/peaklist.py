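"""Assigned CS/DC peak lists.

Reads, validates and writes the assigned (residue, ¹⁵N chemical shift,
¹⁵N-¹H dipolar coupling) peak lists that PISA-wheel fitting consumes, and
exposes the six reference phospholamban datasets as packaged fixtures.

Native format is whitespace/tab-separated with a header line
(``res cs dc [intensity] [status] [group]``); a SPARKY-style ``.list``
reader (``label w1 w2`` columns) is provided for interoperability.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path

VALID_STATUS = ("unique", "overlapped", "ambiguous")

TABLE1_DATASETS = ("PLN", "pPLN", "PLN_SERCA_E2", "pPLN_SERCA_E2",
                   "PLN_SERCA_E1", "pPLN_SERCA_E1")

_LABEL_RE = re.compile(r"^([A-Za-z])(\d+)$")


class PeakListError(ValueError):
    """Malformed peak-list content."""


@dataclass(frozen=True)
class Peak:
    """One assigned amide resonance.

    ``residue_label`` is a one-letter residue code plus a 1-based sequence
    number (``"L31"``).  ``cs`` is the anisotropic ¹⁵N chemical shift in ppm
    and ``dc`` the ¹⁵N-¹H dipolar coupling in kHz, both on the flipped-
    bicelle (doubled) scale.  ``status`` flags resonances that are
    overlapped with another residue (shared CS/DC values) or whose
    assignment is ambiguous; ambiguous alternatives share an
    ``ambiguity_group`` identifier.
    """

    residue_label: str
    cs: float
    dc: float
    intensity: float | None = None
    status: str = "unique"
    ambiguity_group: str | None = None

    def __post_init__(self) -> None:
        if not _LABEL_RE.match(self.residue_label):
            raise PeakListError(
                f"residue label {self.residue_label!r} does not parse to a "
                "one-letter code plus sequence number")
        if self.status not in VALID_STATUS:
            raise PeakListError(f"unknown peak status {self.status!r}")
        if not 0.0 <= self.cs <= 250.0:
            raise PeakListError(
                f"{self.residue_label}: CS {self.cs} ppm outside [0, 250]")
        if not -12.0 <= self.dc <= 12.0:
            raise PeakListError(
                f"{self.residue_label}: DC {self.dc} kHz outside [-12, 12]")

    @property
    def residue_number(self) -> int:
        return int(_LABEL_RE.match(self.residue_label).group(2))

    @property
    def residue_code(self) -> str:
        return _LABEL_RE.match(self.residue_label).group(1)


@dataclass
class PeakList:
    """Ordered collection of assigned peaks for one dataset."""

    dataset_id: str
    peaks: list[Peak]
    reference_residue: str = "L31"

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for p in self.peaks:
            if p.status == "unique":
                if p.residue_label in seen:
                    raise PeakListError(
                        f"duplicate unique assignment for {p.residue_label}")
                seen.add(p.residue_label)

    def __len__(self) -> int:
        return len(self.peaks)

    def __iter__(self):
        return iter(self.peaks)

    @property
    def residue_numbers(self) -> list[int]:
        return [p.residue_number for p in self.peaks]

    @property
    def reference_number(self) -> int:
        return int(_LABEL_RE.match(self.reference_residue).group(2))

    def require_nonempty(self) -> "PeakList":
        if not self.peaks:
            raise PeakListError(f"peak list {self.dataset_id!r} is empty")
        return self


def _parse_native_row(parts: list[str], lineno: int) -> Peak:
    if len(parts) < 3:
        raise PeakListError(f"line {lineno}: expected at least "
                            f"'res cs dc', got {parts!r}")
    label = parts[0]
    status = "unique"
    if label.endswith("*"):
        label, status = label[:-1], "overlapped"
    cs_s, dc_s = parts[1], parts[2]
    if cs_s.endswith("*") or dc_s.endswith("*"):
        status = "overlapped"
        cs_s, dc_s = cs_s.rstrip("*"), dc_s.rstrip("*")
    try:
        cs, dc = float(cs_s), float(dc_s)
    except ValueError as exc:
        raise PeakListError(f"line {lineno}: non-numeric CS/DC "
                            f"{parts[1]!r} {parts[2]!r}") from exc
    intensity = None
    group = None
    rest = parts[3:]
    if rest and rest[0] not in VALID_STATUS:
        if rest[0] != "-":
            try:
                intensity = float(rest[0])
            except ValueError as exc:
                raise PeakListError(
                    f"line {lineno}: expected intensity, got "
                    f"{rest[0]!r}") from exc
        rest = rest[1:]
    if rest:
        status = rest[0]
        rest = rest[1:]
    if rest and rest[0] != "-":
        group = rest[0]
    return Peak(residue_label=label, cs=cs, dc=dc, intensity=intensity,
                status=status, ambiguity_group=group)


def parse_peaklist(path, format: str = "tsv", dataset_id: str | None = None,
                   reference_residue: str = "L31") -> PeakList:
    """Read a peak list from ``path``.

    ``format="tsv"`` is the native dialect; ``format="sparky_list"`` reads
    a SPARKY-style ``.list`` file whose columns are assignment label, ¹⁵N
    shift (w1, ppm) and dipolar coupling (w2, kHz).
    """
    path = Path(path)
    text = path.read_text()
    lines = [(i + 1, ln.strip()) for i, ln in enumerate(text.splitlines())]
    lines = [(i, ln) for i, ln in lines if ln and not ln.startswith("#")]
    if format == "sparky_list":
        # drop the "Assignment  w1  w2" banner if present
        if lines and lines[0][1].lower().split()[0] in ("assignment",):
            lines = lines[1:]
        peaks = []
        for lineno, ln in lines:
            parts = ln.split()
            if len(parts) < 3:
                raise PeakListError(f"line {lineno}: malformed SPARKY row {ln!r}")
            label = parts[0].split("N-H")[0].split("N-")[0].rstrip("N")
            peaks.append(_parse_native_row([label, parts[1], parts[2]], lineno))
    elif format == "tsv":
        if lines and lines[0][1].split()[0].lower() in ("res", "residue", "label"):
            lines = lines[1:]
        peaks = [_parse_native_row(ln.split(), lineno) for lineno, ln in lines]
    else:
        raise ValueError(f"unknown format {format!r}")
    if not peaks:
        raise PeakListError(f"{path}: no peaks found")
    return PeakList(dataset_id=dataset_id or path.stem, peaks=peaks,
                    reference_residue=reference_residue)


def write_peaklist(pl: PeakList, path, format: str = "tsv") -> None:
    """Write a peak list; ``parse_peaklist(write_peaklist(pl))`` round-trips
    every field."""
    path = Path(path)
    rows = []
    if format == "tsv":
        rows.append("res\tcs\tdc\tintensity\tstatus\tgroup")
        for p in pl.peaks:
            rows.append("\t".join([
                p.residue_label, f"{p.cs:.4f}", f"{p.dc:.4f}",
                "-" if p.intensity is None else f"{p.intensity:.6g}",
                p.status, p.ambiguity_group or "-",
            ]))
    elif format == "sparky_list":
        rows.append("Assignment     w1      w2")
        for p in pl.peaks:
            rows.append(f"{p.residue_label}N-H  {p.cs:.4f}  {p.dc:.4f}")
    else:
        raise ValueError(f"unknown format {format!r}")
    path.write_text("\n".join(rows) + "\n")


def _read_native_intensity(tok: str):
    return None if tok == "-" else float(tok)


def _load_table1() -> dict[str, list[Peak]]:
    text = resources.files("pisawheel.data").joinpath("table1.tsv").read_text()
    lines = [ln for ln in text.splitlines() if ln.strip() and not ln.startswith("#")]
    header = lines[0].split("\t")
    cols = {name: k for k, name in enumerate(header)}
    out: dict[str, list[Peak]] = {d: [] for d in TABLE1_DATASETS}
    for ln in lines[1:]:
        parts = ln.split("\t")
        label = parts[0]
        for ds in TABLE1_DATASETS:
            cs_s = parts[cols[f"{ds}_cs"]]
            dc_s = parts[cols[f"{ds}_dc"]]
            if cs_s == "-" or dc_s == "-":
                continue
            status = "overlapped" if cs_s.endswith("*") or dc_s.endswith("*") else "unique"
            out[ds].append(Peak(residue_label=label,
                                cs=float(cs_s.rstrip("*")),
                                dc=float(dc_s.rstrip("*")),
                                status=status))
    return out


def table1_fixture(dataset_id: str, include_overlapped: bool = True) -> PeakList:
    """One of the six packaged reference datasets.

    Overlapped resonances (asterisks in the source table) are retained by
    default as independent data points sharing CS/DC values, since they
    were fit as assigned resonances; pass ``include_overlapped=False`` to
    drop them.
    """
    if dataset_id not in TABLE1_DATASETS:
        raise KeyError(f"unknown dataset {dataset_id!r}; "
                       f"valid ids: {', '.join(TABLE1_DATASETS)}")
    peaks = _load_table1()[dataset_id]
    if not include_overlapped:
        peaks = [p for p in peaks if p.status != "overlapped"]
    return PeakList(dataset_id=dataset_id, peaks=list(peaks),
                    reference_residue="L31")
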