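"""Input/output for peptide-level HDX-MS data and fitted results.

The tool works entirely with plain-text files:

* **RFU table** -- one row per peptide, whitespace- or tab-delimited, with a
  one-line header ``start end sequence rfu_t1 ... rfu_tn``.  Labelling
  timepoints (minutes) are supplied separately because the file header does
  not encode them.
* **k_ch table** -- per-residue intrinsic (chemical) exchange rates in
  min^-1: ``residue aa kch``, with ``NA`` for residues that carry no
  exchangeable backbone amide (prolines and the protein N-terminus).
* **result artefacts** -- TSV tables (per-replicate lnP, per-residue
  summary, per-replicate model RFU) and a JSON run summary.

Residue numbering is 1-based and spans are closed intervals, matching
conventional HDX peptide reporting.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import TYPE_CHECKING, Iterable, Mapping, Sequence

import numpy as np

if TYPE_CHECKING:  # pragma: no cover - type-only imports, avoid cycles
    from .autovalidation import ValidationReport
    from .optimizer import ReplicateEnsemble

AMINO_ACIDS = frozenset("ACDEFGHIKLMNPQRSTVWY")

__all__ = [
    "AMINO_ACIDS",
    "HDXError",
    "ParseError",
    "ValidationError",
    "Peptide",
    "Dataset",
    "ExchangeCompetentSet",
    "IntrinsicRateTable",
    "read_rfu_table",
    "write_rfu_table",
    "read_kch_file",
    "write_kch_file",
    "read_replicate_lnp",
    "write_results",
]


class HDXError(Exception):
    """Base class for all errors raised by hdxsolver."""


class ParseError(HDXError):
    """A file could not be parsed (malformed row/field)."""


class ValidationError(HDXError):
    """Parsed content violates a domain invariant."""


@dataclass(frozen=True)
class Peptide:
    """One proteolytic peptide with its fractional-uptake time series.

    ``start``/``end`` are 1-based inclusive residue numbers; ``rfu`` holds
    one relative-fractional-uptake value per labelling timepoint, each in
    [0, 1].
    """

    id: int
    start: int
    end: int
    sequence: str
    rfu: tuple[float, ...]

    def __post_init__(self) -> None:
        if self.end < self.start:
            raise ValidationError(
                f"peptide {self.id}: end ({self.end}) < start ({self.start})"
            )
        if len(self.sequence) != self.end - self.start + 1:
            raise ValidationError(
                f"peptide {self.id}: sequence length {len(self.sequence)} does not "
                f"match span {self.start}-{self.end} "
                f"({self.end - self.start + 1} residues)"
            )
        bad = set(self.sequence) - AMINO_ACIDS
        if bad:
            raise ValidationError(
                f"peptide {self.id}: unknown residue code(s) {sorted(bad)}"
            )
        for v in self.rfu:
            if not (0.0 <= v <= 1.0) or math.isnan(v):
                raise ValidationError(
                    f"peptide {self.id}: RFU value {v!r} outside [0, 1]"
                )

    @property
    def span(self) -> range:
        return range(self.start, self.end + 1)

    @property
    def n_residues(self) -> int:
        return self.end - self.start + 1

    def competent_residues(self, n_term_exclusion: int = 1) -> tuple[int, ...]:
        """Residues of this peptide that carry observable amide deuterium.

        The first ``n_term_exclusion`` residues (back-exchanging amino
        terminus, default 1) and all prolines are excluded.
        """
        out = []
        for offset, aa in enumerate(self.sequence):
            if offset < n_term_exclusion:
                continue
            if aa == "P":
                continue
            out.append(self.start + offset)
        return tuple(out)


@dataclass
class Dataset:
    """A set of peptides over one protein region -- the optimisation unit."""

    protein_id: str
    timepoints: tuple[float, ...]
    peptides: list[Peptide]
    n_term_exclusion: int = 1

    def __post_init__(self) -> None:
        self.timepoints = tuple(float(t) for t in self.timepoints)
        if any(t <= 0 for t in self.timepoints):
            raise ValidationError("timepoints must be strictly positive")
        if any(b <= a for a, b in zip(self.timepoints, self.timepoints[1:])):
            raise ValidationError("timepoints must be strictly increasing")
        seen: set[tuple[int, int, str]] = set()
        aa_by_residue: dict[int, str] = {}
        for p in self.peptides:
            key = (p.start, p.end, p.sequence)
            if key in seen:
                raise ValidationError(
                    f"duplicate peptide {p.start}-{p.end} {p.sequence}"
                )
            seen.add(key)
            if len(p.rfu) != len(self.timepoints):
                raise ValidationError(
                    f"peptide {p.id}: {len(p.rfu)} RFU values for "
                    f"{len(self.timepoints)} timepoints"
                )
            for r, aa in zip(p.span, p.sequence):
                if aa_by_residue.setdefault(r, aa) != aa:
                    raise ValidationError(
                        f"residue {r}: conflicting amino acids "
                        f"{aa_by_residue[r]!r} vs {aa!r} between peptides"
                    )
        self._aa_by_residue = aa_by_residue

    @property
    def residues(self) -> tuple[int, ...]:
        """Union of all peptide spans, sorted."""
        return tuple(sorted(self._aa_by_residue))

    @property
    def residue_aa(self) -> Mapping[int, str]:
        return dict(self._aa_by_residue)

    @property
    def competent_residues(self) -> tuple[int, ...]:
        out: set[int] = set()
        for p in self.peptides:
            out.update(p.competent_residues(self.n_term_exclusion))
        return tuple(sorted(out))

    def peptide_competent(self, peptide: Peptide) -> tuple[int, ...]:
        return peptide.competent_residues(self.n_term_exclusion)


@dataclass(frozen=True)
class ExchangeCompetentSet:
    """The subset of a dataset's residues that carry observable deuterium."""

    residues: frozenset[int]

    @classmethod
    def from_dataset(cls, dataset: Dataset) -> "ExchangeCompetentSet":
        return cls(frozenset(dataset.competent_residues))


@dataclass
class IntrinsicRateTable:
    """Per-residue intrinsic chemical exchange rates k_ch (min^-1).

    ``entries`` maps residue number to ``(amino_acid, k_ch)``; residues with
    no exchangeable amide (proline, protein N-terminus) carry ``None``.
    """

    entries: dict[int, tuple[str, float | None]]
    pD: float | None = None
    temperature: float | None = None

    def __post_init__(self) -> None:
        for res, (aa, k) in self.entries.items():
            if aa == "P" and k is not None:
                raise ValidationError(f"residue {res}: proline cannot carry a rate")
            if k is not None and k <= 0:
                raise ValidationError(f"residue {res}: k_ch must be positive, got {k}")

    def rate(self, residue: int) -> float | None:
        entry = self.entries.get(residue)
        return None if entry is None else entry[1]

    @property
    def residues(self) -> tuple[int, ...]:
        return tuple(sorted(self.entries))

    def exchanging_residues(self) -> tuple[int, ...]:
        return tuple(sorted(r for r, (_, k) in self.entries.items() if k is not None))


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------


def _split_nonempty_lines(path: Path) -> list[tuple[int, list[str]]]:
    rows = []
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        stripped = line.strip()
        if not stripped or stripped.startswith("#"):
            continue
        rows.append((lineno, stripped.split()))
    return rows


def read_rfu_table(
    path: str | Path,
    timepoints: Sequence[float],
    protein_id: str | None = None,
    n_term_exclusion: int = 1,
) -> Dataset:
    """Read a peptide RFU table into a validated :class:`Dataset`.

    Each data row is ``start end sequence rfu_1 ... rfu_n`` with exactly one
    RFU value per entry of ``timepoints``.  A header line starting with
    ``start`` is permitted and skipped.  Rows violating any invariant raise
    :class:`ParseError`/:class:`ValidationError` naming the offending row.
    """
    path = Path(path)
    if not path.exists():
        raise ParseError(f"no such file: {path}")
    rows = _split_nonempty_lines(path)
    if rows and rows[0][1][0].lower() == "start":
        rows = rows[1:]
    if not rows:
        raise ParseError(f"{path}: no peptides")
    n_t = len(timepoints)
    peptides: list[Peptide] = []
    for idx, (lineno, fields) in enumerate(rows):
        if len(fields) != 3 + n_t:
            raise ParseError(
                f"{path}:{lineno}: expected 3 + {n_t} fields "
                f"(start end sequence rfu...), got {len(fields)}"
            )
        try:
            start, end = int(fields[0]), int(fields[1])
        except ValueError as exc:
            raise ParseError(f"{path}:{lineno}: non-integer start/end field") from exc
        try:
            rfu = tuple(float(v) for v in fields[3:])
        except ValueError as exc:
            raise ParseError(f"{path}:{lineno}: non-numeric RFU field") from exc
        try:
            peptides.append(
                Peptide(id=idx, start=start, end=end, sequence=fields[2], rfu=rfu)
            )
        except ValidationError as exc:
            raise ValidationError(f"{path}:{lineno}: {exc}") from exc
    return Dataset(
        protein_id=protein_id or path.stem,
        timepoints=tuple(timepoints),
        peptides=peptides,
        n_term_exclusion=n_term_exclusion,
    )


def write_rfu_table(dataset: Dataset, path: str | Path) -> None:
    path = Path(path)
    lines = ["\t".join(["start", "end", "sequence"]
                       + [f"rfu_{t:g}" for t in dataset.timepoints])]
    for p in dataset.peptides:
        lines.append(
            "\t".join([str(p.start), str(p.end), p.sequence]
                      + [f"{v:.17g}" for v in p.rfu])
        )
    path.write_text("\n".join(lines) + "\n")


def read_kch_file(path: str | Path) -> IntrinsicRateTable:
    """Read a per-residue intrinsic-rate table (``residue aa kch``).

    ``NA``/``-`` marks residues with no exchangeable amide.  Duplicate
    residue numbers and negative rates are rejected.
    """
    path = Path(path)
    if not path.exists():
        raise ParseError(f"no such file: {path}")
    rows = _split_nonempty_lines(path)
    if rows and rows[0][1][0].lower() in {"residue", "res"}:
        rows = rows[1:]
    entries: dict[int, tuple[str, float | None]] = {}
    pD = temperature = None
    for lineno, fields in rows:
        if len(fields) < 3:
            raise ParseError(f"{path}:{lineno}: expected 'residue aa kch'")
        try:
            res = int(fields[0])
        except ValueError as exc:
            raise ParseError(f"{path}:{lineno}: non-integer residue number") from exc
        aa = fields[1].upper()
        raw = fields[2]
        if raw.upper() in {"NA", "NAN", "-", "NONE"}:
            k: float | None = None
        else:
            try:
                k = float(raw)
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: non-numeric k_ch {raw!r}") from exc
            if k <= 0:
                raise ValidationError(
                    f"{path}:{lineno}: k_ch must be positive, got {k}"
                )
        if aa == "P":
            k = None
        if res in entries:
            raise ValidationError(f"{path}: duplicate entry for residue {res}")
        entries[res] = (aa, k)
    return IntrinsicRateTable(entries=entries, pD=pD, temperature=temperature)


def write_kch_file(table: IntrinsicRateTable, path: str | Path) -> None:
    path = Path(path)
    lines = ["residue\taa\tkch"]
    if table.pD is not None:
        lines.insert(0, f"# pD={table.pD:g} temperature={table.temperature:g}K kch in min^-1")
    for res in table.residues:
        aa, k = table.entries[res]
        lines.append(f"{res}\t{aa}\t" + ("NA" if k is None else f"{k:.17g}"))
    path.write_text("\n".join(lines) + "\n")


def read_replicate_lnp(path: str | Path) -> tuple[tuple[int, ...], np.ndarray]:
    """Read a per-replicate lnP table back into (residues, replicate x residue)."""
    path = Path(path)
    rows = _split_nonempty_lines(path)
    if not rows:
        raise ParseError(f"{path}: empty lnP table")
    header = rows[0][1]
    if header[0] != "replicate":
        raise ParseError(f"{path}: expected header starting with 'replicate'")
    try:
        residues = tuple(int(c.removeprefix("res_")) for c in header[1:])
    except ValueError as exc:
        raise ParseError(f"{path}: malformed residue column names") from exc
    data = []
    for lineno, fields in rows[1:]:
        if len(fields) != len(header):
            raise ParseError(f"{path}:{lineno}: wrong number of columns")
        data.append([float(v) for v in fields[1:]])
    return residues, np.asarray(data, dtype=float)


# ---------------------------------------------------------------------------
# result writing
# ---------------------------------------------------------------------------


def _sig4(x: float) -> float:
    """Round to 4 significant figures for display copies of JSON values."""
    if x == 0 or not math.isfinite(x):
        return x
    return float(f"{x:.4g}")


def write_results(
    ensemble: "ReplicateEnsemble",
    report: "ValidationReport",
    outdir: str | Path,
    model_rfu: Mapping[int, np.ndarray] | None = None,
    dataset: Dataset | None = None,
) -> dict[str, Path]:
    """Write all result artefacts for one optimisation run.

    Emits ``replicate_lnp.tsv`` (replicate x residue, full double
    precision), ``residue_summary.tsv`` (median lnP, IQR, dR-matrix,
    collapse flag), ``model_rfu.tsv`` (per-replicate model RFU per peptide,
    if ``model_rfu`` is given), ``validation_matrix.tsv`` and
    ``summary.json``.  Returns the mapping of artefact name to path.
    """
    if ensemble.lnp.shape[0] == 0:
        raise ValidationError("cannot write an empty ensemble")
    outdir = Path(outdir)
    try:
        outdir.mkdir(parents=True, exist_ok=True)
    except OSError as exc:  # unwritable parent etc.
        raise HDXError(f"cannot create output directory {outdir}: {exc}") from exc

    paths: dict[str, Path] = {}

    lnp_path = outdir / "replicate_lnp.tsv"
    header = ["replicate"] + [f"res_{r}" for r in ensemble.residues]
    lines = ["\t".join(header)]
    for i, row in enumerate(ensemble.lnp):
        lines.append("\t".join([str(i)] + [f"{v:.17g}" for v in row]))
    lnp_path.write_text("\n".join(lines) + "\n")
    paths["replicate_lnp"] = lnp_path

    med = np.median(ensemble.lnp, axis=0)
    q75, q25 = np.percentile(ensemble.lnp, [75, 25], axis=0)
    iqr = q75 - q25
    delta = report.delta_r if report is not None else {}
    summary_path = outdir / "residue_summary.tsv"
    lines = ["residue\tmedian_lnp\tiqr\tdelta_r_matrix\tcollapse"]
    for j, r in enumerate(ensemble.residues):
        d = delta.get(r)
        lines.append(
            f"{r}\t{med[j]:.17g}\t{iqr[j]:.17g}\t"
            + ("NA" if d is None else f"{d:.17g}")
            + f"\t{int(iqr[j] >= 20.0)}"
        )
    summary_path.write_text("\n".join(lines) + "\n")
    paths["residue_summary"] = summary_path

    if model_rfu is not None and dataset is not None:
        rfu_path = outdir / "model_rfu.tsv"
        head = ["replicate", "peptide", "start", "end"] + [
            f"rfu_{t:g}" for t in dataset.timepoints
        ]
        lines = ["\t".join(head)]
        for rep, mat in sorted(model_rfu.items()):
            for p, row in zip(dataset.peptides, np.atleast_2d(mat)):
                lines.append(
                    "\t".join(
                        [str(rep), str(p.id), str(p.start), str(p.end)]
                        + [f"{v:.17g}" for v in row]
                    )
                )
        rfu_path.write_text("\n".join(lines) + "\n")
        paths["model_rfu"] = rfu_path

    if report is not None and report.matrix is not None:
        m_path = outdir / "validation_matrix.tsv"
        np.savetxt(m_path, report.matrix.matrix, fmt="%.17g", delimiter="\t")
        paths["validation_matrix"] = m_path

    summary = {
        "protein_id": dataset.protein_id if dataset is not None else None,
        "replicates": int(ensemble.lnp.shape[0]),
        "seeds": [int(s) for s in ensemble.seeds],
        "converged": [bool(c) for c in ensemble.converged],
        "settings": ensemble.settings_dict(),
        "r_hat_matrix": None,
        "classification": None,
    }
    if report is not None and report.matrix is not None:
        summary["r_hat_matrix"] = float(report.matrix.r_hat)
        summary["r_hat_matrix_display"] = _sig4(float(report.matrix.r_hat))
        summary["classification"] = report.classification
    json_path = outdir / "summary.json"
    json_path.write_text(json.dumps(summary, indent=2) + "\n")
    paths["summary"] = json_path
    return paths
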