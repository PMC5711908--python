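"""Aligned plastid sequences, homopolymer masking and haplotype collapsing.

The unit of analysis is a multiple-sequence alignment of concatenated
plastid loci together with per-sample metadata (region, status, collection
year, coordinates).  Sequences are collapsed to haplotypes after masking
alignment columns whose only variation is mononucleotide run length —
polyA/T/G/C stutter is not treated as a phylogenetic character, while
substitutions inside such runs are retained.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from Bio import SeqIO

VALID_CHARS = frozenset("ACGT-N")

METADATA_COLUMNS = ["sample_id", "region", "status", "year", "lon", "lat"]


class AlignmentError(ValueError):
    """Sequences violate alignment invariants (unequal lengths etc.)."""


class InputError(ValueError):
    """Malformed input files (duplicate ids, unknown characters ...)."""


@dataclass(frozen=True)
class SampleRecord:
    """Metadata for one accession."""

    sample_id: str
    region: str | None = None
    status: str | None = None
    year: int | None = None
    lon: float | None = None
    lat: float | None = None

    def __post_init__(self):
        if self.lon is not None and not -180.0 <= self.lon <= 180.0:
            raise InputError(f"{self.sample_id}: lon {self.lon} out of [-180, 180]")
        if self.lat is not None and not -90.0 <= self.lat <= 90.0:
            raise InputError(f"{self.sample_id}: lat {self.lat} out of [-90, 90]")


@dataclass
class Alignment:
    """Equal-length aligned sequences over {A,C,G,T,-,N} plus metadata.

    ``sites`` is a (n_samples, L) array of single characters; ``masked`` is a
    boolean vector of length L marking columns excluded from all downstream
    comparisons (homopolymer length variation).  Site coordinates in reports
    are 1-based and inclusive.
    """

    samples: list[SampleRecord]
    sites: np.ndarray
    masked: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        self.sites = np.asarray(self.sites, dtype="U1")
        if self.sites.ndim != 2:
            raise AlignmentError("sites must be a 2-D character matrix")
        if self.sites.shape[0] != len(self.samples):
            raise AlignmentError(
                f"{len(self.samples)} metadata records but {self.sites.shape[0]} sequences"
            )
        if self.length == 0:
            raise AlignmentError("alignment has zero columns")
        ids = [s.sample_id for s in self.samples]
        if len(set(ids)) != len(ids):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise InputError(f"duplicate sample ids: {', '.join(dup)}")
        bad = set(np.unique(self.sites)) - VALID_CHARS
        if bad:
            raise InputError(f"unknown alignment characters: {', '.join(sorted(bad))}")
        if self.masked is None:
            self.masked = np.zeros(self.length, dtype=bool)
        else:
            self.masked = np.asarray(self.masked, dtype=bool)
            if self.masked.shape != (self.length,):
                raise AlignmentError("mask length does not match alignment length")

    @property
    def n(self) -> int:
        return len(self.samples)

    @property
    def length(self) -> int:
        return self.sites.shape[1]

    @property
    def sample_ids(self) -> list[str]:
        return [s.sample_id for s in self.samples]

    def subset(self, sample_ids) -> "Alignment":
        """Row subset preserving order of ``sample_ids``."""
        index = {s.sample_id: i for i, s in enumerate(self.samples)}
        missing = [sid for sid in sample_ids if sid not in index]
        if missing:
            raise InputError(f"unknown sample ids: {', '.join(missing)}")
        rows = [index[sid] for sid in sample_ids]
        return Alignment(
            samples=[self.samples[i] for i in rows],
            sites=self.sites[rows],
            masked=self.masked.copy(),
        )

    def metadata_frame(self) -> pd.DataFrame:
        return pd.DataFrame([vars(s) for s in self.samples]).rename(
            columns={"sample_id": "sample_id"}
        )


@dataclass
class HaplotypeSet:
    """Partition of samples into identical-sequence classes.

    ``haplotypes`` maps haplotype id (H1, H2, ... in order of first
    appearance) to (representative sequence, member sample ids).
    """

    haplotypes: list[tuple[str, str, list[str]]]

    @property
    def ids(self) -> list[str]:
        return [h for h, _, _ in self.haplotypes]

    @property
    def n_haplotypes(self) -> int:
        return len(self.haplotypes)

    def assignment(self) -> dict[str, str]:
        """sample_id -> haplotype_id."""
        out: dict[str, str] = {}
        for hid, _, members in self.haplotypes:
            for sid in members:
                out[sid] = hid
        return out

    def sequence(self, hid: str) -> str:
        for h, seq, _ in self.haplotypes:
            if h == hid:
                return seq
        raise KeyError(hid)

    def to_frame(self) -> pd.DataFrame:
        assign = self.assignment()
        return pd.DataFrame(
            {"sample_id": list(assign), "haplotype_id": list(assign.values())}
        )


def _parse_year(v):
    if pd.isna(v) or v == "":
        return None
    return int(v)


def _parse_coord(v):
    if pd.isna(v) or v == "":
        return None
    return float(v)


def read_metadata(metadata_path) -> pd.DataFrame:
    meta = pd.read_csv(metadata_path, sep="\t", dtype={"sample_id": str})
    missing = [c for c in ("sample_id",) if c not in meta.columns]
    if missing:
        raise InputError(f"metadata missing required columns: {missing}")
    if meta["sample_id"].duplicated().any():
        dups = meta.loc[meta["sample_id"].duplicated(), "sample_id"].tolist()
        raise InputError(f"duplicate sample ids in metadata: {dups}")
    return meta


def read_alignment(fasta_path, metadata_path) -> Alignment:
    """Join an aligned FASTA with a tab-separated metadata table.

    Every FASTA record must have a metadata row; metadata rows without a
    sequence are ignored (a metadata table may cover several alignments).
    """
    records = list(SeqIO.parse(str(fasta_path), "fasta"))
    if not records:
        raise InputError(f"no FASTA records in {fasta_path}")
    ids = [r.id for r in records]
    if len(set(ids)) != len(ids):
        dup = sorted({i for i in ids if ids.count(i) > 1})
        raise InputError(f"duplicate sequence ids: {', '.join(dup)}")
    lengths = {len(r.seq) for r in records}
    if len(lengths) != 1:
        raise AlignmentError(
            f"sequences are not aligned: lengths {sorted(lengths)} differ"
        )
    meta = read_metadata(metadata_path).set_index("sample_id")
    absent = [i for i in ids if i not in meta.index]
    if absent:
        raise InputError(f"samples missing from metadata: {', '.join(absent)}")

    samples = []
    for sid in ids:
        row = meta.loc[sid]
        samples.append(
            SampleRecord(
                sample_id=sid,
                region=None if pd.isna(row.get("region")) else str(row.get("region")),
                status=None if pd.isna(row.get("status")) else str(row.get("status")),
                year=_parse_year(row.get("year")),
                lon=_parse_coord(row.get("lon")),
                lat=_parse_coord(row.get("lat")),
            )
        )
    sites = np.array([list(str(r.seq).upper()) for r in records], dtype="U1")
    return Alignment(samples=samples, sites=sites)


def _run_spans(row: np.ndarray, min_run: int):
    """Maximal spans (start, stop) of identical non-gap bases, ignoring gaps.

    A gap inside a run of the same base does not break the run: the run is
    defined on the ungapped sequence, and the span covers the aligned columns
    it occupies.
    """
    L = row.shape[0]
    spans = []
    i = 0
    while i < L:
        base = row[i]
        if base in ("-", "N"):
            i += 1
            continue
        j = i + 1
        count = 1
        last = i
        while j < L and (row[j] == base or row[j] == "-"):
            if row[j] == base:
                count += 1
                last = j
            j += 1
        if count >= min_run:
            spans.append((i, last, base))
        i = last + 1
    return spans


def mask_homopolymer_variation(aln: Alignment, min_run: int = 3) -> Alignment:
    """Flag columns whose variation is purely homopolymer length.

    A column is masked when (a) it lies inside a mononucleotide run of length
    >= ``min_run`` in at least one sequence, and (b) the non-missing states
    observed in the column are a subset of {run base, '-'} — i.e. the only
    variation is indel stutter.  Columns with substitutions (a different base
    in any sequence) are kept.  Idempotent.
    """
    if min_run < 2:
        raise InputError(f"min_run must be >= 2, got {min_run}")
    candidate_base: dict[int, set] = {}
    for r in range(aln.n):
        for start, stop, base in _run_spans(aln.sites[r], min_run):
            for c in range(start, stop + 1):
                candidate_base.setdefault(c, set()).add(base)
    masked = aln.masked.copy()
    for c, bases in candidate_base.items():
        col = aln.sites[:, c]
        states = set(col[col != "N"])
        # purely length variation: states within {base, '-'} for one run base
        for base in bases:
            if states <= {base, "-"}:
                masked[c] = True
                break
    return Alignment(samples=list(aln.samples), sites=aln.sites.copy(), masked=masked)


def _compatible(a: np.ndarray, b: np.ndarray) -> bool:
    """Equal at every column where both are non-N."""
    both = (a != "N") & (b != "N")
    return bool(np.all(a[both] == b[both]))


def collapse_haplotypes(aln: Alignment, treat_N_as: str = "missing") -> HaplotypeSet:
    """Group identical sequences (over unmasked sites) into haplotypes.

    ``treat_N_as='missing'``: a sequence containing N joins an existing
    haplotype iff it is compatible (equal at all mutually non-N unmasked
    sites) with exactly one; multi-way compatibility is ambiguous and the
    sequence keeps its own haplotype with a warning.  ``treat_N_as='state'``
    compares N literally.
    """
    if treat_N_as not in ("missing", "state"):
        raise InputError(f"treat_N_as must be 'missing' or 'state', got {treat_N_as!r}")
    keep = ~aln.masked
    reps: list[np.ndarray] = []  # representative rows (unmasked columns only)
    members: list[list[str]] = []
    for r in range(aln.n):
        row = aln.sites[r, keep]
        sid = aln.samples[r].sample_id
        if treat_N_as == "state" or not np.any(row == "N"):
            hit = None
            for k, rep in enumerate(reps):
                if treat_N_as == "missing":
                    if not np.any(rep == "N") and np.array_equal(rep, row):
                        hit = k
                        break
                elif np.array_equal(rep, row):
                    hit = k
                    break
            if hit is None:
                reps.append(row)
                members.append([sid])
            else:
                members[hit].append(sid)
            continue
        # N-containing sequence under the missing policy
        hits = [k for k, rep in enumerate(reps) if _compatible(rep, row)]
        if len(hits) == 1:
            members[hits[0]].append(sid)
        else:
            if len(hits) > 1:
                warnings.warn(
                    f"sample {sid}: ambiguous N-compatibility with "
                    f"{len(hits)} haplotypes; kept as its own haplotype",
                    stacklevel=2,
                )
            reps.append(row)
            members.append([sid])

    full_reps = []
    keep_idx = np.flatnonzero(keep)
    for rep in reps:
        full = np.full(aln.length, "N", dtype="U1")
        full[keep_idx] = rep
        full_reps.append("".join(full))
    return HaplotypeSet(
        haplotypes=[
            (f"H{k + 1}", full_reps[k], members[k]) for k in range(len(reps))
        ]
    )


def frequency_table(
    hset: HaplotypeSet, aln: Alignment, group_by: str = "region"
) -> pd.DataFrame:
    """Haplotype count table: rows = groups, columns = haplotype ids.

    Row sums equal group sample sizes; the grand total is the sample count.
    """
    if group_by not in ("region", "status"):
        raise InputError(f"group_by must be 'region' or 'status', got {group_by!r}")
    assign = hset.assignment()
    rows = []
    for s in aln.samples:
        rows.append((getattr(s, group_by), assign[s.sample_id]))
    df = pd.DataFrame(rows, columns=[group_by, "haplotype_id"])
    table = (
        df.groupby([group_by, "haplotype_id"], dropna=False)
        .size()
        .unstack(fill_value=0)
    )
    return table.reindex(columns=hset.ids, fill_value=0)
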