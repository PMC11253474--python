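"""Streaming VCF input and the tabular results format.

Input is uncompressed VCF 4.x text whose FORMAT includes the AD (allelic
depth) subfield, read from a file path, an open text stream, or stdin.
Samples are matched to experimental roles positionally: the i-th label of
the role string corresponds to the i-th sample column of the VCF.

Output is a VCF-like tab-separated table: ``##``-prefixed provenance lines
(one per pipeline stage, recorded cumulatively), ``##FIELD`` lines that
describe each column, one ``#``-prefixed heading line, then data rows.
Stage output is readable by the merge and plot stages without loss.
"""

from __future__ import annotations

import io
import logging
import math
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence, TextIO, Union

from . import PROGRAM, __version__

logger = logging.getLogger(PROGRAM)

MBS_ROLES = ("R", "D", "Pr", "Pd", "Wr", "Wd")
QTL_ROLES = ("H", "L", "P")

#: bulk roles whose allele counts enter the statistics, per design
MBS_BULKS = ("D", "R")
QTL_BULKS = ("H", "L")

MISSING = "NA"


class VcfFormatError(ValueError):
    """Structural problem with the VCF input (header/sample mismatch)."""


class RoleError(ValueError):
    """Invalid sample-to-role assignment."""


@dataclass(frozen=True)
class SampleRoleMap:
    """Positional mapping of VCF sample columns to experimental roles.

    MBS roles: R (required recessive bulk), D (dominant bulk), Pr/Pd
    (recessive/dominant parent), Wr/Wd (non-mutagenized wild types, used
    only to discard pre-existing alleles).  QTL-seq roles: H and L (both
    required extreme bulks) and P (a resequenced parent).
    """

    roles: tuple[str, ...]
    mode: str  # "mbs" | "qtl"

    def __contains__(self, role: str) -> bool:
        return role in self.roles

    def index_of(self, role: str) -> int:
        return self.roles.index(role)

    @property
    def bulks(self) -> tuple[str, ...]:
        wanted = MBS_BULKS if self.mode == "mbs" else QTL_BULKS
        return tuple(r for r in wanted if r in self.roles)

    @property
    def w_samples(self) -> tuple[str, ...]:
        return tuple(r for r in self.roles if r in ("Wr", "Wd"))


def parse_role_assignment(spec: str, mode: str) -> SampleRoleMap:
    """Parse a comma-separated role string (the ``-d`` option).

    Raises :class:`RoleError` on unknown labels for the mode, duplicate
    labels, or a missing required label (R for mbs; H and L for qtl).
    """
    if mode not in ("mbs", "qtl"):
        raise RoleError(f"unknown analysis mode: {mode!r}")
    if not spec or not spec.strip():
        raise RoleError("empty role assignment")
    labels = tuple(s.strip() for s in spec.split(","))
    valid = MBS_ROLES if mode == "mbs" else QTL_ROLES
    for lab in labels:
        if lab not in valid:
            raise RoleError(
                f"unknown sample role {lab!r} for mode {mode!r}; "
                f"valid roles are {', '.join(valid)}"
            )
    dupes = [lab for lab, k in Counter(labels).items() if k > 1]
    if dupes:
        raise RoleError(f"duplicate sample role(s): {', '.join(dupes)}")
    if mode == "mbs" and "R" not in labels:
        raise RoleError("mbs requires an R sample (the recessive bulk)")
    if mode == "qtl" and not {"H", "L"} <= set(labels):
        raise RoleError("qtl requires both H and L bulks")
    return SampleRoleMap(roles=labels, mode=mode)


@dataclass(frozen=True)
class VariantRecord:
    """One VCF site with per-role allele depths.

    ``depths[role]`` is the AD vector in REF-then-ALTs order; its length is
    ``1 + len(alts)``.
    """

    chrom: str
    pos: int
    ref: str
    alts: tuple[str, ...]
    depths: Mapping[str, tuple[int, ...]]

    @property
    def is_biallelic(self) -> bool:
        return len(self.alts) == 1


Source = Union[str, Path, TextIO]


def _open_source(source: Source):
    """Return (stream, should_close) for a path or an open text stream."""
    if isinstance(source, (str, Path)):
        return open(source, "rt"), True
    return source, False


class VcfReader:
    """Iterate :class:`VariantRecord` objects from uncompressed VCF text.

    By default malformed data lines and sites lacking AD are skipped with a
    logged warning and counted; with ``strict=True`` they abort the run.
    Identical input bytes yield identical record sequences whether the
    source is a pipe, an open stream, or a file path.
    """

    def __init__(self, source: Source, roles: SampleRoleMap, strict: bool = False):
        self.source = source
        self.roles = roles
        self.strict = strict
        self.n_records = 0
        self.n_skipped = 0
        self.skip_reasons: Counter[str] = Counter()
        self.samples: tuple[str, ...] | None = None

    def _skip(self, reason: str, line_no: int, detail: str = "") -> None:
        if self.strict:
            raise VcfFormatError(f"line {line_no}: {reason} {detail}".rstrip())
        self.n_skipped += 1
        self.skip_reasons[reason] += 1
        logger.warning("skipping VCF line %d: %s %s", line_no, reason, detail)

    def __iter__(self) -> Iterator[VariantRecord]:
        stream, close = _open_source(self.source)
        try:
            yield from self._parse(stream)
        finally:
            if close:
                stream.close()

    def _parse(self, stream: TextIO) -> Iterator[VariantRecord]:
        roles = self.roles.roles
        saw_header = False
        for line_no, line in enumerate(stream, start=1):
            line = line.rstrip("\n").rstrip("\r")
            if not line:
                continue
            if line.startswith("##"):
                continue
            if line.startswith("#"):
                cols = line.split("\t")
                samples = tuple(cols[9:])
                if len(samples) != len(roles):
                    raise VcfFormatError(
                        f"VCF has {len(samples)} sample column(s) but "
                        f"{len(roles)} role(s) were assigned"
                    )
                self.samples = samples
                saw_header = True
                continue
            if not saw_header:
                raise VcfFormatError("VCF data encountered before #CHROM header")
            rec = self._parse_line(line, line_no)
            if rec is not None:
                self.n_records += 1
                yield rec

    def _parse_line(self, line: str, line_no: int) -> VariantRecord | None:
        fields = line.split("\t")
        if len(fields) < 9 + len(self.roles.roles):
            self._skip("malformed-line", line_no, "(too few columns)")
            return None
        chrom, pos_s, _id, ref, alt = fields[0], fields[1], fields[2], fields[3], fields[4]
        try:
            pos = int(pos_s)
        except ValueError:
            self._skip("malformed-line", line_no, f"(bad POS {pos_s!r})")
            return None
        if pos < 1 or not ref:
            self._skip("malformed-line", line_no, "(invalid POS/REF)")
            return None
        alts = () if alt in (".", "") else tuple(alt.split(","))
        fmt = fields[8].split(":")
        if "AD" not in fmt:
            self._skip("missing-AD", line_no)
            return None
        ad_idx = fmt.index("AD")
        n_alleles = 1 + len(alts)
        depths: dict[str, tuple[int, ...]] = {}
        for role, value in zip(self.roles.roles, fields[9:]):
            sub = value.split(":")
            if len(sub) <= ad_idx or sub[ad_idx] in (".", ""):
                self._skip("missing-AD", line_no, f"(sample {role})")
                return None
            try:
                ad = tuple(int(x) for x in sub[ad_idx].split(","))
            except ValueError:
                self._skip("malformed-line", line_no, f"(bad AD in {role})")
                return None
            if len(ad) != n_alleles or any(d < 0 for d in ad):
                self._skip("malformed-line", line_no, f"(AD length in {role})")
                return None
            depths[role] = ad
        return VariantRecord(chrom=chrom, pos=pos, ref=ref, alts=alts, depths=depths)


def read_variant_stream(
    source: Source, roles: SampleRoleMap, strict: bool = False
) -> VcfReader:
    """Convenience constructor mirroring the streaming read operation."""
    return VcfReader(source, roles, strict=strict)


# ---------------------------------------------------------------------------
# results format


@dataclass
class ResultHeader:
    """Cumulative header of the VCF-like results format.

    Each pipeline stage appends exactly one provenance line recording the
    program, its version and the full analysis-option string, so the header
    of a final file documents every step that produced it.
    """

    provenance: list[str] = field(default_factory=list)
    columns: list[tuple[str, str]] = field(default_factory=list)

    def add_step(self, options: str) -> None:
        self.provenance.append(
            f"##{PROGRAM}_step={PROGRAM} {options}; version={__version__}"
        )

    @property
    def column_names(self) -> list[str]:
        return [name for name, _ in self.columns]

    def lines(self) -> list[str]:
        out = list(self.provenance)
        for name, desc in self.columns:
            out.append(f'##FIELD=<ID={name},Description="{desc}">')
        out.append("#" + "\t".join(self.column_names))
        return out


def _format_value(v) -> str:
    if v is None:
        return MISSING
    if isinstance(v, bool):
        return "1" if v else "0"
    if isinstance(v, (int,)):
        return str(v)
    if isinstance(v, float):
        if math.isnan(v):
            return MISSING
        # shortest round-trip representation: re-reading restores the value
        return repr(v)
    return str(v)


def write_results(
    rows: Iterable[Mapping[str, object]],
    header: ResultHeader,
    sink: Source,
) -> int:
    """Write header then tab-separated rows; returns the row count.

    Zero rows is legal and yields a header-only file.
    """
    stream, close = (open(sink, "wt"), True) if isinstance(sink, (str, Path)) else (sink, False)
    names = header.column_names
    n = 0
    try:
        for line in header.lines():
            stream.write(line + "\n")
        for row in rows:
            stream.write("\t".join(_format_value(row.get(c)) for c in names) + "\n")
            n += 1
    finally:
        if close:
            stream.close()
    return n


def _parse_value(s: str):
    if s == MISSING:
        return None
    try:
        return int(s)
    except ValueError:
        pass
    try:
        return float(s)
    except ValueError:
        return s


def read_results(source: Source) -> tuple[ResultHeader, list[dict]]:
    """Read a results table back into a header and typed row dicts."""
    stream, close = _open_source(source)
    header = ResultHeader()
    rows: list[dict] = []
    names: list[str] | None = None
    try:
        for line in stream:
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("##FIELD=<ID="):
                body = line[len("##FIELD=<ID="):].rstrip(">")
                name, _, rest = body.partition(",Description=")
                header.columns.append((name, rest.strip('"')))
            elif line.startswith(f"##{PROGRAM}_step="):
                header.provenance.append(line)
            elif line.startswith("##"):
                continue
            elif line.startswith("#"):
                names = line[1:].split("\t")
                if not header.columns:
                    header.columns = [(n, "") for n in names]
            else:
                if names is None:
                    raise VcfFormatError("results data before heading line")
                vals = line.split("\t")
                rows.append({k: _parse_value(v) for k, v in zip(names, vals)})
    finally:
        if close:
            stream.close()
    return header, rows
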