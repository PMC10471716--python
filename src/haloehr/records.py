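"""Patient records, code vocabulary, bucket discretization, and matrix encoding.

A patient record is a sequence of clinical visits, each a set of medical codes
plus optional lab measurements and an inter-visit gap in days.  For modelling,
a record is flattened into a binary matrix whose rows are

    [start, label, visit 1, ..., visit T, end, pad, ...]

over a unified code vocabulary that contains the medical codes, one code per
static/phenotype label, one code per bucket of every continuous-variable
discretization scheme, and dedicated start/end codes.  Continuous values (labs,
gaps) enter the matrix as bucket codes and are reconstituted on decoding by
uniform sampling within the bucket interval.
"""

from __future__ import annotations

import hashlib
import json
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import yaml

logger = logging.getLogger(__name__)

START_CODE = "<start>"
END_CODE = "<end>"
GAP_VARIABLE = "gap_days"

CODE_KINDS = ("medical", "label", "gap_bucket", "lab_bucket", "start", "end")


class UnknownCodeError(KeyError):
    """A code string is absent from the vocabulary."""


class OutOfRangeError(ValueError):
    """A continuous value falls outside its bucket scheme's range."""


class MalformedRecordError(ValueError):
    """A records file line cannot be parsed into a patient record."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass
class Visit:
    """One encounter: a set of medical codes, labs, and the gap since the
    previous visit (``None`` on a record's first visit)."""

    codes: set = field(default_factory=set)
    labs: list = field(default_factory=list)  # list of (name, value) pairs
    gap_days: float | None = None

    def __eq__(self, other):
        if not isinstance(other, Visit):
            return NotImplemented
        return (
            self.codes == other.codes
            and sorted(self.labs) == sorted(other.labs)
            and _float_eq(self.gap_days, other.gap_days)
        )


def _float_eq(a, b):
    if a is None or b is None:
        return a is None and b is None
    return abs(a - b) < 1e-9


@dataclass
class PatientRecord:
    patient_id: str
    labels: set = field(default_factory=set)
    visits: list = field(default_factory=list)
    truncated: bool = False

    @property
    def n_visits(self) -> int:
        return len(self.visits)


@dataclass
class BucketScheme:
    """Discretization of one continuous variable into K left-closed/right-open
    buckets ``[e_{k-1}, e_k)`` defined by strictly increasing edges."""

    variable: str
    edges: np.ndarray

    def __post_init__(self):
        self.edges = np.asarray(self.edges, dtype=float)
        if self.edges.ndim != 1 or self.edges.size < 2:
            raise ValueError("a bucket scheme needs at least two edges")
        if not np.all(np.diff(self.edges) > 0):
            raise ValueError(f"edges for {self.variable!r} must be strictly increasing")

    @property
    def n_buckets(self) -> int:
        return self.edges.size - 1

    @property
    def kind(self) -> str:
        return "gap_bucket" if self.variable == GAP_VARIABLE else "lab_bucket"

    def bucket_code(self, k: int) -> str:
        """Vocabulary code string for 1-based bucket index ``k``."""
        if not 1 <= k <= self.n_buckets:
            raise OutOfRangeError(f"bucket index {k} outside 1..{self.n_buckets}")
        return f"{self.variable}|b{k}"


def discretize_value(value: float, scheme: BucketScheme) -> int:
    """Map a value to its 1-based bucket index; ``[e_0, e_K)`` coverage only."""
    e = scheme.edges
    if not (e[0] <= value < e[-1]):
        raise OutOfRangeError(
            f"{scheme.variable}={value} outside [{e[0]}, {e[-1]})"
        )
    return int(np.searchsorted(e, value, side="right"))


def reconstitute_value(k: int, scheme: BucketScheme, rng: np.random.Generator) -> float:
    """Draw a value uniformly from bucket ``k`` of the scheme."""
    if not 1 <= int(k) <= scheme.n_buckets:
        raise OutOfRangeError(f"bucket index {k} outside 1..{scheme.n_buckets}")
    return float(rng.uniform(scheme.edges[k - 1], scheme.edges[k]))


def equal_frequency_edges(values, n_buckets: int) -> np.ndarray:
    """Quantile bucket edges from data (used when no clinician edges are given).

    The last edge is nudged up so the maximum observed value stays in range.
    """
    v = np.sort(np.asarray(values, dtype=float))
    if v.size < 2:
        raise ValueError("need at least two values to build edges")
    qs = np.linspace(0, 1, n_buckets + 1)
    edges = np.quantile(v, qs)
    edges[-1] = np.nextafter(edges[-1], np.inf)
    edges = np.unique(edges)
    if edges.size < 2:
        raise ValueError("values are degenerate; cannot build buckets")
    return edges


def heart_rate_scheme() -> BucketScheme:
    """A 20-bucket heart-rate scheme (bpm) with clinically equivalent groupings:
    bucket 1 is [0, 40) and bucket 7 is [90, 100)."""
    edges = [0, 40, 50, 60, 70, 80, 90, 100, 110, 120, 130, 140,
             150, 160, 170, 180, 200, 250, 300, 350, 400]
    return BucketScheme("heart_rate", np.asarray(edges, dtype=float))


# ---------------------------------------------------------------------------
# Vocabulary
# ---------------------------------------------------------------------------


@dataclass
class CodeVocabulary:
    """Ordered unified code set.  The stored order is the intra-visit
    autoregressive order used by the code-level model; it is fixed once built
    (a seeded random permutation of the non-special codes, with the start and
    end codes last)."""

    code_strings: list
    kinds: list

    def __post_init__(self):
        if len(self.code_strings) != len(set(self.code_strings)):
            raise ValueError("duplicate code strings in vocabulary")
        if self.kinds.count("start") != 1 or self.kinds.count("end") != 1:
            raise ValueError("vocabulary needs exactly one start and one end code")
        for k in self.kinds:
            if k not in CODE_KINDS:
                raise ValueError(f"unknown code kind {k!r}")
        self._index = {s: i for i, s in enumerate(self.code_strings)}

    @property
    def size(self) -> int:
        return len(self.code_strings)

    def __len__(self) -> int:
        return self.size

    def __contains__(self, code: str) -> bool:
        return code in self._index

    def id_of(self, code: str) -> int:
        try:
            return self._index[code]
        except KeyError:
            raise UnknownCodeError(f"code {code!r} not in vocabulary") from None

    def string_of(self, code_id: int) -> str:
        return self.code_strings[code_id]

    def kind_of(self, code_id: int) -> str:
        return self.kinds[code_id]

    def ids_of_kind(self, *kinds: str) -> np.ndarray:
        return np.array(
            [i for i, k in enumerate(self.kinds) if k in kinds], dtype=int
        )

    @property
    def start_id(self) -> int:
        return self.kinds.index("start")

    @property
    def end_id(self) -> int:
        return self.kinds.index("end")

    def content_hash(self) -> str:
        h = hashlib.sha256()
        for s, k in zip(self.code_strings, self.kinds):
            h.update(f"{s}\t{k}\n".encode())
        return h.hexdigest()


def build_vocabulary(records, schemes=(), seed: int = 0) -> CodeVocabulary:
    """Collect every observed medical code and label, all bucket codes of the
    given schemes, and start/end codes.

    The non-special codes are shuffled by a single seeded permutation fixed at
    build time; two builds from the same inputs and seed are identical.
    """
    records = list(records)
    if not records:
        raise ValueError("cannot build a vocabulary from zero records")
    medical, labels = set(), set()
    for r in records:
        labels.update(r.labels)
        for v in r.visits:
            medical.update(v.codes)
    entries = [(c, "medical") for c in sorted(medical)]
    entries += [(c, "label") for c in sorted(labels)]
    for sch in schemes:
        entries += [(sch.bucket_code(k), sch.kind) for k in range(1, sch.n_buckets + 1)]
    strings = [e[0] for e in entries]
    if len(strings) != len(set(strings)):
        raise ValueError("duplicate code strings across kinds")
    if START_CODE in strings or END_CODE in strings:
        raise ValueError("records may not use the reserved start/end code strings")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(entries))
    entries = [entries[i] for i in order]
    # Special codes lead the intra-visit order: the end code's conditional is
    # then P(stop | history) directly — the record's stop hazard — rather than
    # a conjunction over every other code's absence, which autoregressive
    # sampling would otherwise have to thread through all C-2 columns.
    entries = [(START_CODE, "start"), (END_CODE, "end")] + entries
    return CodeVocabulary([e[0] for e in entries], [e[1] for e in entries])


# ---------------------------------------------------------------------------
# Matrix encoding
# ---------------------------------------------------------------------------


@dataclass
class RecordMatrix:
    """Binary record matrix of shape (T_max+3, C) with rows
    [start, label, visit 1..T, end, pad...]; ``true_length`` counts content
    visits T (so the end row sits at index T+2)."""

    matrix: np.ndarray
    true_length: int

    @property
    def n_rows(self) -> int:
        """Number of meaningful rows, start through end (= T+3)."""
        return self.true_length + 3


def _scheme_map(schemes):
    return {s.variable: s for s in schemes}


def encode_record(
    record: PatientRecord,
    vocab: CodeVocabulary,
    schemes=(),
    t_max: int = 10,
) -> RecordMatrix:
    """Encode a patient record as a padded binary matrix.

    Labs and gaps become their bucket codes inside the visit rows.  Records
    longer than ``t_max`` visits are truncated (earliest visits kept) with a
    logged warning; the end row is always present.
    """
    by_var = _scheme_map(schemes)
    visits = record.visits
    if len(visits) > t_max:
        logger.warning(
            "record %s has %d visits; truncating to %d",
            record.patient_id, len(visits), t_max,
        )
        visits = visits[:t_max]
    T = len(visits)
    R = np.zeros((t_max + 3, vocab.size), dtype=np.float32)
    R[0, vocab.start_id] = 1.0
    for lab_code in record.labels:
        R[1, vocab.id_of(lab_code)] = 1.0
    for t, visit in enumerate(visits):
        row = R[2 + t]
        for c in visit.codes:
            row[vocab.id_of(c)] = 1.0
        for name, value in visit.labs:
            sch = by_var.get(name)
            if sch is None:
                raise UnknownCodeError(f"no bucket scheme for lab {name!r}")
            row[vocab.id_of(sch.bucket_code(discretize_value(value, sch)))] = 1.0
        if visit.gap_days is not None and t > 0:
            sch = by_var.get(GAP_VARIABLE)
            if sch is None:
                raise UnknownCodeError("record has visit gaps but no gap scheme given")
            row[vocab.id_of(sch.bucket_code(discretize_value(visit.gap_days, sch)))] = 1.0
    R[2 + T, vocab.end_id] = 1.0
    return RecordMatrix(R, T)


def decode_record(
    rm: RecordMatrix,
    vocab: CodeVocabulary,
    schemes=(),
    rng: np.random.Generator | None = None,
    patient_id: str = "decoded",
) -> PatientRecord:
    """Inverse of :func:`encode_record`; bucket codes are reconstituted to
    continuous values by uniform sampling within the bucket."""
    if rng is None:
        rng = np.random.default_rng(0)
    by_var = _scheme_map(schemes)
    bucket_lookup = {}  # code_id -> (scheme, bucket index)
    for sch in by_var.values():
        for k in range(1, sch.n_buckets + 1):
            code = sch.bucket_code(k)
            if code in vocab:
                bucket_lookup[vocab.id_of(code)] = (sch, k)

    R = rm.matrix
    label_ids = set(np.flatnonzero(R[1]).tolist())
    labels = set()
    for i in label_ids:
        if vocab.kind_of(i) != "label":
            raise ValueError(f"non-label code {vocab.string_of(i)!r} in label row")
        labels.add(vocab.string_of(i))

    visits, truncated = [], True
    end_id = vocab.end_id
    for t in range(2, R.shape[0]):
        ones = np.flatnonzero(R[t])
        if R[t, end_id]:
            truncated = False
            break
        codes, labs, gap_buckets = set(), [], {}
        for i in ones:
            kind = vocab.kind_of(int(i))
            if kind == "medical":
                codes.add(vocab.string_of(int(i)))
            elif kind in ("gap_bucket", "lab_bucket"):
                sch, k = bucket_lookup[int(i)]
                if kind == "gap_bucket":
                    gap_buckets.setdefault(sch.variable, []).append(k)
                else:
                    labs.append((sch.variable, reconstitute_value(k, sch, rng)))
            else:
                raise ValueError(
                    f"{kind} code {vocab.string_of(int(i))!r} inside a content visit"
                )
        gap = None
        if gap_buckets:
            ks = sorted(gap_buckets[GAP_VARIABLE])
            if len(ks) > 1:
                warnings.warn(
                    f"visit {t - 2} carries {len(ks)} gap buckets; using the lowest",
                    stacklevel=2,
                )
            if t > 2:
                gap = reconstitute_value(ks[0], by_var[GAP_VARIABLE], rng)
        visits.append(Visit(codes=codes, labs=sorted(labs), gap_days=gap))
    if truncated:
        warnings.warn("no end code found; record decoded as truncated", stacklevel=2)
    return PatientRecord(patient_id, labels, visits, truncated=truncated)


# ---------------------------------------------------------------------------
# File formats
# ---------------------------------------------------------------------------


def record_to_json(record: PatientRecord) -> dict:
    return {
        "patient_id": record.patient_id,
        "labels": sorted(record.labels),
        "visits": [
            {
                "codes": sorted(v.codes),
                "labs": [{"name": n, "value": float(x)} for n, x in v.labs],
                "gap_days": None if v.gap_days is None else float(v.gap_days),
            }
            for v in record.visits
        ],
    }


def record_from_json(obj: dict) -> PatientRecord:
    visits = [
        Visit(
            codes=set(v.get("codes", [])),
            labs=[(l["name"], float(l["value"])) for l in v.get("labs", [])],
            gap_days=None if v.get("gap_days") is None else float(v["gap_days"]),
        )
        for v in obj["visits"]
    ]
    return PatientRecord(str(obj["patient_id"]), set(obj.get("labels", [])), visits)


def write_records(path, records) -> int:
    """Stream records to JSON Lines; returns the number written."""
    n = 0
    with open(path, "w", encoding="utf-8") as fh:
        for r in records:
            fh.write(json.dumps(record_to_json(r), sort_keys=True))
            fh.write("\n")
            n += 1
    return n


def iter_records(path):
    """Stream patient records from a JSONL file, one at a time."""
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            try:
                yield record_from_json(json.loads(line))
            except (json.JSONDecodeError, KeyError, TypeError, ValueError) as exc:
                raise MalformedRecordError(
                    f"{path}: malformed record on line {lineno}: {exc}"
                ) from exc


def read_records(path) -> list:
    return list(iter_records(path))


def write_vocabulary(path, vocab: CodeVocabulary) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("code_id\tcode_string\tkind\n")
        for i, (s, k) in enumerate(zip(vocab.code_strings, vocab.kinds)):
            fh.write(f"{i}\t{s}\t{k}\n")


def read_vocabulary(path) -> CodeVocabulary:
    strings, kinds = [], []
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != ["code_id", "code_string", "kind"]:
            raise MalformedRecordError(f"{path}: unexpected vocabulary header {header}")
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) != 3:
                raise MalformedRecordError(f"{path}: malformed vocabulary line {lineno}")
            code_id, s, k = parts
            if int(code_id) != len(strings):
                raise MalformedRecordError(f"{path}: non-contiguous code_id on line {lineno}")
            strings.append(s)
            kinds.append(k)
    return CodeVocabulary(strings, kinds)


def read_bucket_schemes(path) -> list:
    """Load bucket schemes from YAML/JSON: a list of {variable, edges}."""
    with open(path, encoding="utf-8") as fh:
        data = yaml.safe_load(fh)
    if isinstance(data, dict):
        data = [data]
    return [BucketScheme(d["variable"], np.asarray(d["edges"], dtype=float)) for d in data]


def write_bucket_schemes(path, schemes) -> None:
    data = [
        {"variable": s.variable, "edges": [float(e) for e in s.edges]} for s in schemes
    ]
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(data, fh, sort_keys=False)
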