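"""Readers and writers for the plain-text file dialects.

Formats
-------
pedigree        one record per line: ``id sire dam`` (``0`` = unknown parent)
array genotypes ``id g1 ... gL`` with g in {0,1,2,9}; 9 = missing
read counts     two consecutive lines per individual:
                ``id r1 ... rL`` (reference counts) then ``id a1 ... aL``
                (alternative counts)
marker map      ``locus chrom position inA`` with inA in {0,1}; positions are
                1-based base pairs, strictly increasing within a chromosome
outputs         dosages (id + L reals in [0,2]); calls (0/1/2, 9 = no call);
                phased alleles (two lines per individual, paternal then
                maternal, 0/1, 9 = no call); optional 4-state probabilities
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .pedigree import Pedigree, PedigreeError, UNKNOWN

MISSING = 9
NO_CALL = 9


# ----------------------------------------------------------------------
@dataclass
class MarkerMap:
    """Marker positions and membership in the sparse multi-locus set A."""

    locus_ids: list[str]
    chromosome: list[str]
    position: np.ndarray  # base pairs, int64
    in_set_a: np.ndarray  # bool

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=np.int64)
        self.in_set_a = np.asarray(self.in_set_a, dtype=bool)
        if np.any(self.position < 0):
            raise ValueError("marker positions must be non-negative")
        for chrom in set(self.chromosome):
            pos = self.position[[c == chrom for c in self.chromosome]]
            if np.any(np.diff(pos) <= 0):
                raise ValueError(
                    f"positions must be strictly increasing on chromosome {chrom}"
                )

    def __len__(self) -> int:
        return len(self.locus_ids)

    @property
    def set_a_indices(self) -> np.ndarray:
        return np.flatnonzero(self.in_set_a)

    @property
    def set_b_indices(self) -> np.ndarray:
        return np.flatnonzero(~self.in_set_a)

    @classmethod
    def uniform(cls, n_loci: int, length_bp: int = 100_000_000,
                n_set_a: int | None = None, chromosome: str = "1") -> "MarkerMap":
        """Evenly spaced markers; every ``L/n_set_a``-th marker is in set A."""
        pos = np.linspace(1, length_bp, n_loci).astype(np.int64)
        pos = np.maximum.accumulate(pos)  # guard against ties at small scales
        if np.any(np.diff(pos) <= 0):
            pos = np.arange(1, n_loci + 1, dtype=np.int64)
        in_a = np.zeros(n_loci, dtype=bool)
        if n_set_a:
            idx = np.linspace(0, n_loci - 1, n_set_a).round().astype(int)
            in_a[np.unique(idx)] = True
        else:
            in_a[:] = True
        ids = [f"m{i + 1}" for i in range(n_loci)]
        return cls(ids, [chromosome] * n_loci, pos, in_a)


@dataclass
class ObservedData:
    """Per-individual array genotypes and sequence read counts.

    Arrays are aligned to a pedigree's individual order and a marker map's
    locus order. An individual may have array data, read data, both, or
    neither (all-missing genotypes and zero reads).
    """

    genotypes: np.ndarray  # (N, L) int8, MISSING = 9
    ref_reads: np.ndarray  # (N, L) int32
    alt_reads: np.ndarray  # (N, L) int32

    def __post_init__(self) -> None:
        if np.any(self.ref_reads < 0) or np.any(self.alt_reads < 0):
            raise ValueError("read counts must be non-negative")

    @property
    def n_individuals(self) -> int:
        return self.genotypes.shape[0]

    @property
    def n_loci(self) -> int:
        return self.genotypes.shape[1]

    @classmethod
    def empty(cls, n_individuals: int, n_loci: int) -> "ObservedData":
        return cls(
            genotypes=np.full((n_individuals, n_loci), MISSING, dtype=np.int8),
            ref_reads=np.zeros((n_individuals, n_loci), dtype=np.int32),
            alt_reads=np.zeros((n_individuals, n_loci), dtype=np.int32),
        )

    def subset_loci(self, idx: np.ndarray) -> "ObservedData":
        return ObservedData(
            genotypes=self.genotypes[:, idx],
            ref_reads=self.ref_reads[:, idx],
            alt_reads=self.alt_reads[:, idx],
        )


# ----------------------------------------------------------------------
def _tokenized_lines(path) -> list[list[str]]:
    out = []
    with open(path) as fh:
        for line in fh:
            toks = line.split()
            if toks:
                out.append(toks)
    return out


def read_pedigree(path) -> Pedigree:
    """Read a whitespace-delimited ``id sire dam`` pedigree file."""
    records = []
    for toks in _tokenized_lines(path):
        if len(toks) != 3:
            raise PedigreeError(f"expected 3 columns, got {len(toks)}: {toks}")
        records.append((toks[0], toks[1], toks[2]))
    return Pedigree.from_records(records)


def write_pedigree(path, ped: Pedigree) -> None:
    with open(path, "w") as fh:
        for i, name in enumerate(ped.ids):
            s = ped.ids[ped.sire[i]] if ped.sire[i] >= 0 else UNKNOWN
            d = ped.ids[ped.dam[i]] if ped.dam[i] >= 0 else UNKNOWN
            fh.write(f"{name} {s} {d}\n")


def read_marker_map(path) -> MarkerMap:
    ids, chroms, pos, in_a = [], [], [], []
    for toks in _tokenized_lines(path):
        if len(toks) != 4:
            raise ValueError(f"map line needs 4 columns: {toks}")
        ids.append(toks[0])
        chroms.append(toks[1])
        pos.append(int(toks[2]))
        if toks[3] not in ("0", "1"):
            raise ValueError(f"inA flag must be 0 or 1, got {toks[3]!r}")
        in_a.append(toks[3] == "1")
    return MarkerMap(ids, chroms, np.array(pos), np.array(in_a))


def write_marker_map(path, mmap: MarkerMap) -> None:
    with open(path, "w") as fh:
        for i in range(len(mmap)):
            fh.write(
                f"{mmap.locus_ids[i]} {mmap.chromosome[i]} "
                f"{mmap.position[i]} {int(mmap.in_set_a[i])}\n"
            )


def read_observations(genotype_path, read_path, mmap: MarkerMap,
                      ped: Pedigree) -> ObservedData:
    """Read array genotypes and/or read counts, aligned to ``ped`` and ``mmap``.

    Either path may be ``None``. Individuals present in the pedigree but in
    neither file carry all-missing genotypes and zero reads.
    """
    L = len(mmap)
    obs = ObservedData.empty(len(ped), L)
    if genotype_path is not None:
        for toks in _tokenized_lines(genotype_path):
            if len(toks) != L + 1:
                raise ValueError(
                    f"genotype line for {toks[0]!r} has {len(toks) - 1} loci, "
                    f"map has {L}"
                )
            g = np.array(toks[1:], dtype=np.int16)
            if not np.all(np.isin(g, (0, 1, 2, MISSING))):
                raise ValueError(f"invalid genotype code for {toks[0]!r}")
            obs.genotypes[ped.index_of(toks[0])] = g.astype(np.int8)
    if read_path is not None:
        lines = _tokenized_lines(read_path)
        if len(lines) % 2:
            raise ValueError("read-count file must have two lines per individual")
        for ref_toks, alt_toks in zip(lines[::2], lines[1::2]):
            if ref_toks[0] != alt_toks[0]:
                raise ValueError(
                    f"read-count line pair mismatch: {ref_toks[0]!r} vs {alt_toks[0]!r}"
                )
            if len(ref_toks) != L + 1 or len(alt_toks) != L + 1:
                raise ValueError(f"read-count columns do not match map for {ref_toks[0]!r}")
            i = ped.index_of(ref_toks[0])
            ref = np.array(ref_toks[1:], dtype=np.int64)
            alt = np.array(alt_toks[1:], dtype=np.int64)
            if np.any(ref < 0) or np.any(alt < 0):
                raise ValueError(f"negative read count for {ref_toks[0]!r}")
            obs.ref_reads[i] = ref
            obs.alt_reads[i] = alt
    return obs


def write_observations(genotype_path, read_path, ped: Pedigree,
                       obs: ObservedData) -> None:
    if genotype_path is not None:
        with open(genotype_path, "w") as fh:
            for i, name in enumerate(ped.ids):
                fh.write(name + " " + " ".join(map(str, obs.genotypes[i])) + "\n")
    if read_path is not None:
        with open(read_path, "w") as fh:
            for i, name in enumerate(ped.ids):
                fh.write(name + " " + " ".join(map(str, obs.ref_reads[i])) + "\n")
                fh.write(name + " " + " ".join(map(str, obs.alt_reads[i])) + "\n")


# ----------------------------------------------------------------------
def write_dosages(path, ids, dosages: np.ndarray, decimals: int = 4) -> None:
    with open(path, "w") as fh:
        for name, row in zip(ids, dosages):
            fh.write(name + " " + " ".join(f"{x:.{decimals}f}" for x in row) + "\n")


def read_dosages(path) -> tuple[list[str], np.ndarray]:
    ids, rows = [], []
    for toks in _tokenized_lines(path):
        ids.append(toks[0])
        rows.append([float(x) for x in toks[1:]])
    return ids, np.array(rows)


def write_calls(path, ids, calls: np.ndarray) -> None:
    with open(path, "w") as fh:
        for name, row in zip(ids, calls):
            fh.write(name + " " + " ".join(map(str, row)) + "\n")


def read_calls(path) -> tuple[list[str], np.ndarray]:
    ids, rows = [], []
    for toks in _tokenized_lines(path):
        ids.append(toks[0])
        rows.append([int(x) for x in toks[1:]])
    return ids, np.array(rows, dtype=np.int8)


def write_phase(path, ids, paternal: np.ndarray, maternal: np.ndarray) -> None:
    """Two lines per individual: paternal then maternal alleles (0/1, 9=no call)."""
    with open(path, "w") as fh:
        for name, pat, mat in zip(ids, paternal, maternal):
            fh.write(name + " " + " ".join(map(str, pat)) + "\n")
            fh.write(name + " " + " ".join(map(str, mat)) + "\n")


def read_phase(path) -> tuple[list[str], np.ndarray, np.ndarray]:
    lines = _tokenized_lines(path)
    ids, pats, mats = [], [], []
    for pat_toks, mat_toks in zip(lines[::2], lines[1::2]):
        ids.append(pat_toks[0])
        pats.append([int(x) for x in pat_toks[1:]])
        mats.append([int(x) for x in mat_toks[1:]])
    return ids, np.array(pats, dtype=np.int8), np.array(mats, dtype=np.int8)


def write_probabilities(path, ids, probs: np.ndarray, decimals: int = 6) -> None:
    """Dump the 4-state phased-genotype probabilities, one line per state.

    Line format: ``id state p1 ... pL`` with state in {aa, aA, Aa, AA}.
    """
    states = ("aa", "aA", "Aa", "AA")
    with open(path, "w") as fh:
        for name, block in zip(ids, probs):
            for k, state in enumerate(states):
                fh.write(
                    f"{name} {state} "
                    + " ".join(f"{x:.{decimals}f}" for x in block[:, k])
                    + "\n"
                )


def write_outputs(prefix, ids, probs: np.ndarray, dosages: np.ndarray,
                  calls: np.ndarray, paternal: np.ndarray, maternal: np.ndarray,
                  write_probs: bool = False) -> dict[str, str]:
    """Write the standard output bundle next to ``prefix``.

    Returns a mapping of output kind to path.
    """
    paths = {
        "dosages": f"{prefix}.dosages.txt",
        "calls": f"{prefix}.calls.txt",
        "phase": f"{prefix}.phase.txt",
    }
    write_dosages(paths["dosages"], ids, dosages)
    write_calls(paths["calls"], ids, calls)
    write_phase(paths["phase"], ids, paternal, maternal)
    if write_probs:
        paths["probabilities"] = f"{prefix}.probs.txt"
        write_probabilities(paths["probabilities"], ids, probs)
    return paths


# ----------------------------------------------------------------------
def write_segregation(path, ids, mmap: MarkerMap, seg: np.ndarray,
                      loci: np.ndarray | None = None, decimals: int = 6) -> None:
    """Text dump ``id locus p_pp p_pm p_mp p_mm`` (the hybrid checkpoint)."""
    if loci is None:
        loci = np.arange(seg.shape[1])
    with open(path, "w") as fh:
        for i, name in enumerate(ids):
            for k, j in enumerate(loci):
                row = " ".join(f"{x:.{decimals}f}" for x in seg[i, k])
                fh.write(f"{name} {mmap.locus_ids[j]} {row}\n")


def read_segregation(path, ids, mmap: MarkerMap) -> tuple[np.ndarray, np.ndarray]:
    """Read a segregation checkpoint; returns (seg (N, LA, 4), locus indices)."""
    index = {name: i for i, name in enumerate(ids)}
    locus_index = {name: j for j, name in enumerate(mmap.locus_ids)}
    entries: dict[int, dict[int, np.ndarray]] = {}
    loci_seen: set[int] = set()
    for toks in _tokenized_lines(path):
        i = index[toks[0]]
        j = locus_index[toks[1]]
        entries.setdefault(i, {})[j] = np.array(toks[2:6], dtype=float)
        loci_seen.add(j)
    loci = np.array(sorted(loci_seen))
    seg = np.full((len(ids), len(loci), 4), 0.25)
    for i, per_locus in entries.items():
        for k, j in enumerate(loci):
            if j in per_locus:
                seg[i, k] = per_locus[j]
    return seg, loci


def write_params(path, mmap: MarkerMap, params) -> None:
    """Audit dump ``locus p eps delta gamma`` (gamma blank for the last locus)."""
    with open(path, "w") as fh:
        for j in range(len(mmap)):
            gamma = f"{params.gamma[j]:.6g}" if j < len(params.gamma) else "NA"
            fh.write(
                f"{mmap.locus_ids[j]} {params.p[j]:.6g} {params.eps[j]:.6g} "
                f"{params.delta[j]:.6g} {gamma}\n"
            )


def write_vcf(path, ped: Pedigree, mmap: MarkerMap, calls: np.ndarray,
              paternal: np.ndarray, maternal: np.ndarray) -> None:
    """Minimal VCF export of called genotypes, phased (``|``) where both
    parental alleles were called, unphased (``/``) otherwise."""
    visible = [i for i, name in enumerate(ped.ids) if not name.startswith("__anon")]
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(ped.ids[i] for i in visible) + "\n")
        for j in range(len(mmap)):
            fields = [mmap.chromosome[j], str(mmap.position[j]), mmap.locus_ids[j],
                      "A", "B", ".", "PASS", ".", "GT"]
            for i in visible:
                p, m, g = paternal[i, j], maternal[i, j], calls[i, j]
                if p != NO_CALL and m != NO_CALL:
                    gt = f"{p}|{m}"
                elif g != NO_CALL:
                    gt = {0: "0/0", 1: "0/1", 2: "1/1"}[int(g)]
                else:
                    gt = "./."
                fields.append(gt)
            fh.write("\t".join(fields) + "\n")
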