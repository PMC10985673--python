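"""Bit-sampling LSH over reference k-mers.

Each of ``l`` hash tables samples ``h`` fixed base positions of a 32-mer;
the table row of a k-mer is the concatenation of the 2-bit symbols at those
positions, extracted directly from the packed 64-bit encoding. Rows hold at
most ``b`` pointers into an append-only k-mer array ``K``; every stored
k-mer also carries a 2-byte taxon label and a genome-occurrence count.

Two k-mers at Hamming distance ``d`` share a given table row with
probability ``(1 - d/k)**h``, hence share at least one of the ``l`` rows
with probability

    rho(d) = 1 - (1 - (1 - d/k)**h)**l

which is the analytic model behind parameter selection. Lookups follow the
<= b*l candidate pointers, compute true Hamming distances, and therefore
never report a false positive.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from lshtax.seqcodec import EncodedKmer, hamming_distance_values

__all__ = [
    "LshParams",
    "HashSpec",
    "LshIndex",
    "KmerMatch",
    "rho",
    "expected_matches",
    "suggest_params",
    "round_half_up",
]

_NO_SLOT = np.int64(-1)


def round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def default_d_max(p: int) -> int:
    """Default maximum voting distance: round-half-up of 3p/2 (5 for p=3)."""
    return round_half_up(3 * p / 2)


@dataclass(frozen=True)
class LshParams:
    """Index geometry and matching thresholds.

    ``h=15`` with ``b=7``, ``l=2`` is the documented production default
    (sized for ~2^33 reference k-mers); tests and desk-scale runs use
    ``h=11`` so tables stay in the tens of megabytes.
    """

    k: int = 32
    h: int = 15
    l: int = 2
    b: int = 7
    p: int = 3
    d_max: int | None = None

    def __post_init__(self) -> None:
        if not 1 <= self.h < self.k:
            raise ValueError(f"need 1 <= h < k, got h={self.h}, k={self.k}")
        if self.l < 1 or self.b < 1:
            raise ValueError("l and b must be >= 1")
        if self.d_max is None:
            object.__setattr__(self, "d_max", default_d_max(self.p))
        if not 0 <= self.p <= self.d_max <= self.k:
            raise ValueError(f"need 0 <= p <= d_max <= k, got p={self.p}, d_max={self.d_max}")

    @property
    def num_rows(self) -> int:
        return 1 << (2 * self.h)


@dataclass(frozen=True)
class HashSpec:
    """Per-table sampled base positions, reproducible from a seed."""

    positions: tuple[tuple[int, ...], ...]
    seed: int

    @classmethod
    def generate(cls, params: LshParams, seed: int = 0) -> "HashSpec":
        rng = np.random.default_rng(seed)
        pos = tuple(
            tuple(int(p) for p in rng.choice(params.k, size=params.h, replace=False))
            for _ in range(params.l)
        )
        return cls(pos, seed)

    def __post_init__(self) -> None:
        for table in self.positions:
            if len(set(table)) != len(table):
                raise ValueError("hash positions within a table must be distinct")


@dataclass(frozen=True)
class KmerMatch:
    ref_index: int
    distance: int
    taxon: int


def rho(d: float, params: LshParams) -> float:
    """Probability that two k-mers at Hamming distance ``d`` share at least
    one table row. ``d`` may be fractional (expected distance d_norm * k)."""
    if not 0 <= d <= params.k:
        raise ValueError(f"d must be in [0, k], got {d}")
    per_table = (1.0 - d / params.k) ** params.h
    return 1.0 - (1.0 - per_table) ** params.l


def expected_matches(L: int, d_norm: float, params: LshParams) -> float:
    """Expected number of matching k-mers on a read of length ``L`` whose
    per-base distance to the closest reference is ``d_norm``:
    ``(L - k + 1) * rho(d_norm * k)``."""
    if L < params.k:
        raise ValueError(f"read length {L} shorter than k={params.k}")
    if not 0.0 <= d_norm <= 1.0:
        raise ValueError(f"d_norm must be in [0, 1], got {d_norm}")
    return (L - params.k + 1) * rho(d_norm * params.k, params)


def suggest_params(num_kmers: int, memory_budget: int | None = None) -> LshParams:
    """Pick the smallest ``h`` whose tables can hold ``num_kmers`` pointers.

    Deterministic simplification of the library-sizing heuristic: with
    b=7, l=2 fixed, choose the smallest h >= 8 such that the total slot
    count across tables, ``2**(2h) * b * l``, is at least ``num_kmers``;
    if a memory budget (bytes) is given, lower h until
    ``slots*4 + num_kmers*(8 + 2)`` fits, erroring below h=8.
    """
    if num_kmers < 1:
        raise ValueError("num_kmers must be >= 1")
    b, l = 7, 2
    h = 8
    while (1 << (2 * h)) * b * l < num_kmers and h < 31:
        h += 1
    if memory_budget is not None:
        def mem(hh: int) -> int:
            slots = (1 << (2 * hh)) * b * l
            return slots * 4 + num_kmers * (8 + 2)

        while h >= 8 and mem(h) > memory_budget:
            h -= 1
        if h < 8:
            raise ValueError(
                f"memory budget {memory_budget} B cannot fit tables at minimum h=8"
            )
    return LshParams(k=32, h=h, l=l, b=b)


class LshIndex:
    """Bucketed bit-sampling LSH index with per-k-mer labels and counts.

    Stored k-mers live in the append-only array ``kmer_values`` (the array
    K); each of the ``l`` tables is a ``2^(2h) x b`` pointer matrix (-1 =
    empty). Row overflow is resolved reservoir-style so retained pointers
    are a uniform subset of all insertion attempts for that row,
    independent of genome processing order.
    """

    def __init__(self, params: LshParams, spec: HashSpec | None = None, seed: int = 0):
        if spec is None:
            spec = HashSpec.generate(params, seed)
        if len(spec.positions) != params.l:
            raise ValueError("spec table count != params.l")
        self.params = params
        self.spec = spec
        self._rng = np.random.default_rng(np.random.SeedSequence([seed, 0xB0C]))
        self._kmers: np.ndarray = np.empty(0, dtype=np.uint64)
        self._n = 0
        self.labels: np.ndarray = np.empty(0, dtype=np.uint16)
        self.counts: np.ndarray = np.empty(0, dtype=np.uint32)
        self.tables = [
            np.full((params.num_rows, params.b), _NO_SLOT, dtype=np.int64)
            for _ in range(params.l)
        ]
        self.attempts = [np.zeros(params.num_rows, dtype=np.int64) for _ in range(params.l)]
        self._sorted_cache: tuple[np.ndarray, np.ndarray] | None = None

    # ------------------------------------------------------------------ size

    def __len__(self) -> int:
        return self._n

    @property
    def kmer_values(self) -> np.ndarray:
        return self._kmers[: self._n]

    def _grow(self, extra: int) -> None:
        need = self._n + extra
        if need <= self._kmers.size:
            return
        cap = max(need, 2 * self._kmers.size, 1024)
        for name, dtype in (("_kmers", np.uint64),):
            arr = np.empty(cap, dtype=dtype)
            arr[: self._n] = getattr(self, name)[: self._n]
            setattr(self, name, arr)
        for name, dtype in (("labels", np.uint16), ("counts", np.uint32)):
            arr = np.zeros(cap, dtype=dtype)
            arr[: self._n] = getattr(self, name)[: self._n]
            setattr(self, name, arr)

    # ----------------------------------------------------------------- hash

    def hash_values(self, values: np.ndarray, table: int) -> np.ndarray:
        """Row indices of packed k-mer values for one table: the 2-bit
        symbols at the table's sampled positions, concatenated in position
        order."""
        positions = self.spec.positions[table]
        rows = np.zeros(values.shape, dtype=np.uint64)
        for j, pos in enumerate(positions):
            sym = (values >> np.uint64(2 * pos)) & np.uint64(3)
            rows |= sym << np.uint64(2 * j)
        return rows

    def table_hash(self, x: EncodedKmer | int, table: int) -> int:
        if not 0 <= table < self.params.l:
            raise IndexError(f"table index {table} out of range")
        value = x.value if isinstance(x, EncodedKmer) else int(x)
        return int(self.hash_values(np.array([value], dtype=np.uint64), table)[0])

    # --------------------------------------------------------------- insert

    def _candidate_pointers(self, rows: list[int]) -> np.ndarray:
        ptrs = np.concatenate(
            [self.tables[i][rows[i]] for i in range(self.params.l)]
        )
        return ptrs[ptrs >= 0]

    def insert(self, x: EncodedKmer | int) -> bool:
        """Insert one k-mer; returns True if it was newly appended to K.

        A k-mer already present (locatable via its hash rows) is not
        duplicated. On a full row the new pointer replaces a uniformly
        random occupied slot with probability b/m, where m counts insertion
        attempts the row has seen including this one (reservoir sampling),
        else the pointer is dropped for that table.
        """
        value = np.uint64(x.value if isinstance(x, EncodedKmer) else int(x))
        rows = [int(self.hash_values(np.array([value]), i)[0]) for i in range(self.params.l)]
        ptrs = self._candidate_pointers(rows)
        if ptrs.size and (self._kmers[ptrs] == value).any():
            return False
        self._grow(1)
        idx = self._n
        self._kmers[idx] = value
        self.labels[idx] = 0
        self.counts[idx] = 0
        self._n += 1
        self._sorted_cache = None
        b = self.params.b
        for i, row in enumerate(rows):
            self.attempts[i][row] += 1
            slots = self.tables[i][row]
            free = np.flatnonzero(slots == _NO_SLOT)
            if free.size:
                slots[free[0]] = idx
            else:
                m = int(self.attempts[i][row])
                if self._rng.random() < b / m:
                    slots[int(self._rng.integers(b))] = idx
        return True

    def bulk_insert(self, values: np.ndarray) -> None:
        """Vectorized insertion of distinct k-mer values into an empty index.

        Distributionally equivalent to sequential :meth:`insert` of the
        values in random order: per row, the retained pointers are a
        uniform b-subset of that row's candidates.
        """
        if self._n:
            raise ValueError("bulk_insert requires an empty index")
        values = np.unique(np.asarray(values, dtype=np.uint64))
        n = values.size
        self._grow(n)
        self._kmers[:n] = values
        self._n = n
        self._sorted_cache = None
        b = self.params.b
        for i in range(self.params.l):
            rows = self.hash_values(values, i).astype(np.int64)
            priority = self._rng.random(n)
            order = np.lexsort((priority, rows))
            sorted_rows = rows[order]
            # rank of each entry within its row group
            starts = np.flatnonzero(np.diff(sorted_rows, prepend=-1))
            group_start = np.repeat(starts, np.diff(np.append(starts, n)))
            rank = np.arange(n) - group_start
            keep = rank < b
            self.tables[i][sorted_rows[keep], rank[keep]] = order[keep]
            np.add.at(self.attempts[i], rows, 1)

    # --------------------------------------------------------------- lookup

    def _sorted(self) -> tuple[np.ndarray, np.ndarray]:
        if self._sorted_cache is None:
            vals = self.kmer_values
            order = np.argsort(vals, kind="stable")
            self._sorted_cache = (vals[order], order)
        return self._sorted_cache

    def find_indices(self, values: np.ndarray) -> np.ndarray:
        """Index into K of each value, or -1 if absent (exact membership,
        independent of table pointers)."""
        svals, order = self._sorted()
        pos = np.searchsorted(svals, values)
        pos_c = np.minimum(pos, max(svals.size - 1, 0))
        found = svals.size > 0
        hit = found & (svals[pos_c] == values) if svals.size else np.zeros(values.shape, bool)
        out = np.full(values.shape, -1, dtype=np.int64)
        if svals.size:
            out[hit] = order[pos_c[hit]]
        return out

    def lookup_batch(self, values: np.ndarray, tie: str = "ref"):
        """Best match per query value among the <= b*l candidates.

        Returns ``(distance, ref_index, taxon)`` arrays; distance is -1
        where no candidate lies within ``d_max``. The reported distance is
        always the true Hamming distance (no false positives). Ties at the
        minimum distance break toward the smallest ref_index
        (``tie='ref'``) or the smallest taxon label then ref_index
        (``tie='label'``, used by the vote collector).
        """
        if tie not in ("ref", "label"):
            raise ValueError("tie must be 'ref' or 'label'")
        values = np.asarray(values, dtype=np.uint64)
        n = values.size
        bl = self.params.b * self.params.l
        cand = np.empty((n, bl), dtype=np.int64)
        for i in range(self.params.l):
            rows = self.hash_values(values, i).astype(np.int64)
            cand[:, i * self.params.b : (i + 1) * self.params.b] = self.tables[i][rows]
        valid = cand >= 0
        safe = np.where(valid, cand, 0)
        dist = hamming_distance_values(self._kmers[safe], values[:, None]).astype(np.uint64)
        big = np.uint64(0xFFFFFFFFFFFFFFFF)
        if tie == "label":
            lab = self.labels[safe].astype(np.uint64)
            key = (dist << np.uint64(56)) | (lab << np.uint64(40)) | safe.astype(np.uint64)
        else:
            key = (dist << np.uint64(56)) | safe.astype(np.uint64)
        key = np.where(valid & (dist <= np.uint64(self.params.d_max)), key, big)
        best = key.min(axis=1)
        none = best == big
        ref = (best & np.uint64(0xFFFFFFFFFF)).astype(np.int64)
        out_d = (best >> np.uint64(56)).astype(np.int16)
        out_d[none] = -1
        ref[none] = -1
        taxon = np.where(none, 0, self.labels[np.where(none, 0, ref)]).astype(np.uint16)
        return out_d, ref, taxon

    def lookup(self, x: EncodedKmer | int) -> KmerMatch | None:
        """Best (minimum true-HD) match for one k-mer, or None if no
        candidate lies within ``d_max``."""
        value = np.array([x.value if isinstance(x, EncodedKmer) else int(x)], dtype=np.uint64)
        d, ref, taxon = self.lookup_batch(value, tie="ref")
        if d[0] < 0:
            return None
        return KmerMatch(ref_index=int(ref[0]), distance=int(d[0]), taxon=int(taxon[0]))

    # ---------------------------------------------------------------- state

    def set_counts(self, values: np.ndarray, counts: np.ndarray) -> None:
        idx = self.find_indices(np.asarray(values, dtype=np.uint64))
        present = idx >= 0
        self.counts[idx[present]] = counts[present]

    # ------------------------------------------------------------- save/load

    def save(self, directory: str | Path) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        meta = {
            "format_version": 1,
            "params": {
                "k": self.params.k,
                "h": self.params.h,
                "l": self.params.l,
                "b": self.params.b,
                "p": self.params.p,
                "d_max": self.params.d_max,
            },
            "hash_positions": [list(t) for t in self.spec.positions],
            "hash_seed": self.spec.seed,
            "num_kmers": self._n,
        }
        (directory / "metadata.json").write_text(json.dumps(meta, indent=2))
        np.save(directory / "kmers.npy", self.kmer_values)
        np.save(directory / "labels.npy", self.labels[: self._n])
        np.save(directory / "counts.npy", self.counts[: self._n])
        for i, table in enumerate(self.tables):
            np.save(directory / f"table{i}.npy", table)
            np.save(directory / f"attempts{i}.npy", self.attempts[i])

    @classmethod
    def load(cls, directory: str | Path) -> "LshIndex":
        directory = Path(directory)
        meta = json.loads((directory / "metadata.json").read_text())
        params = LshParams(**meta["params"])
        spec = HashSpec(
            tuple(tuple(t) for t in meta["hash_positions"]), meta["hash_seed"]
        )
        index = cls(params, spec)
        kmers = np.load(directory / "kmers.npy")
        n = int(meta["num_kmers"])
        index._grow(n)
        index._kmers[:n] = kmers
        index._n = n
        index.labels[:n] = np.load(directory / "labels.npy")
        index.counts[:n] = np.load(directory / "counts.npy")
        index.tables = [np.load(directory / f"table{i}.npy") for i in range(params.l)]
        index.attempts = [np.load(directory / f"attempts{i}.npy") for i in range(params.l)]
        index._sorted_cache = None
        return index
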