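"""MHC class I binding prediction behind a uniform backend interface.

The external backend shells out to a NetMHC-4.0-style executable and parses
its tabular output; the trained model is wrapped, never reimplemented.  The
mock backend is a pure deterministic function of (peptide, allele, seed),
log-uniformly mapped into [1, 50000] nM, so every downstream filter is
testable without model weights.
"""

from __future__ import annotations

import hashlib
import math
import shutil
import subprocess
import tempfile
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

DEFAULT_ALLELES = ("H-2Kb", "H-2Db")  # C57BL/6 class I alleles
STRONG_NM = 500.0  # strong binder: affinity strictly below
NON_BINDER_NM = 5000.0  # non-binder: affinity strictly above

MAX_AFFINITY_NM = 50000.0


@dataclass(frozen=True)
class BindingResult:
    peptide: str
    allele: str
    affinity_nm: float
    percentile_rank: float | None = None

    def __post_init__(self) -> None:
        if not (self.affinity_nm > 0 and math.isfinite(self.affinity_nm)):
            raise ValueError(f"affinity must be finite and positive, got {self.affinity_nm}")


class MockBindingBackend:
    """Deterministic stand-in for a trained binding predictor.

    The affinity is derived from a keyed SHA-256 hash of (seed, peptide,
    allele) mapped log-uniformly onto [1, 50000] nM: bitwise identical
    across runs and platforms for a fixed seed, uncorrelated across
    peptides.
    """

    name = "mock"

    def __init__(self, seed: int = 0):
        self.seed = int(seed)

    def affinity(self, peptide: str, allele: str) -> float:
        digest = hashlib.sha256(f"{self.seed}:{peptide}:{allele}".encode()).digest()
        u = int.from_bytes(digest[:8], "big") / 2**64  # uniform [0, 1)
        return 10.0 ** (u * math.log10(MAX_AFFINITY_NM))

    def predict(self, peptides: Sequence[str], alleles: Sequence[str]) -> list[BindingResult]:
        return [
            BindingResult(p, a, self.affinity(p, a))
            for p in peptides
            for a in alleles
        ]


class ExternalBackendError(RuntimeError):
    pass


class NetMHCBackend:
    """Adapter for an externally installed NetMHC-4.0-style executable.

    Writes the peptide list, invokes ``<executable> -p -f <file> -a
    <allele>`` per allele, and parses the whitespace table (data lines start
    with an integer position; affinity in nM and percentile rank at the
    configured column indices, which match NetMHC 4.0 output).
    """

    name = "external"

    #: internal allele names -> executable's naming
    DEFAULT_ALLELE_MAP = {"H-2Kb": "H-2-Kb", "H-2Db": "H-2-Db"}

    def __init__(
        self,
        executable: str = "netMHC",
        allele_map: Mapping[str, str] | None = None,
        affinity_column: int = 12,
        rank_column: int = 13,
        peptide_column: int = 2,
    ):
        self.executable = executable
        self.allele_map = dict(allele_map or self.DEFAULT_ALLELE_MAP)
        self.affinity_column = affinity_column
        self.rank_column = rank_column
        self.peptide_column = peptide_column

    def predict(self, peptides: Sequence[str], alleles: Sequence[str]) -> list[BindingResult]:
        if shutil.which(self.executable) is None:
            raise ExternalBackendError(f"executable {self.executable!r} not found on PATH")
        results: list[BindingResult] = []
        with tempfile.TemporaryDirectory() as tmp:
            pepfile = Path(tmp) / "peptides.txt"
            pepfile.write_text("".join(p + "\n" for p in peptides))
            for allele in alleles:
                ext_name = self.allele_map.get(allele, allele)
                proc = subprocess.run(
                    [self.executable, "-p", "-f", str(pepfile), "-a", ext_name],
                    capture_output=True,
                    text=True,
                )
                if proc.returncode != 0:
                    raise ExternalBackendError(
                        f"{self.executable} exited {proc.returncode} for allele {allele}: "
                        f"{proc.stderr.strip()[:500]}"
                    )
                results.extend(self._parse_output(proc.stdout, allele))
        return results

    def _parse_output(self, text: str, allele: str) -> list[BindingResult]:
        out = []
        for line in text.splitlines():
            fields = line.split()
            if not fields or not fields[0].isdigit():
                continue  # headers, separators, summaries
            try:
                peptide = fields[self.peptide_column]
                affinity = float(fields[self.affinity_column])
                rank = float(fields[self.rank_column])
            except (IndexError, ValueError) as exc:
                raise ExternalBackendError(
                    f"unparseable output line for allele {allele}: {line!r}"
                ) from exc
            out.append(BindingResult(peptide, allele, affinity, rank))
        return out


def predict_binding(
    peptides: Iterable[str],
    alleles: Sequence[str] = DEFAULT_ALLELES,
    backend: MockBindingBackend | NetMHCBackend | None = None,
) -> list[BindingResult]:
    """Predict affinities for every (peptide, allele) pair.

    Peptides are deduplicated (binding is sequence-determined) and must be
    8-14 residues.  The returned matrix is complete: one result per pair.
    """
    if backend is None:
        backend = MockBindingBackend()
    unique = sorted(set(peptides))
    for p in unique:
        if not 8 <= len(p) <= 14:
            raise ValueError(f"peptide length {len(p)} outside 8-14: {p!r}")
    results = backend.predict(unique, list(alleles))
    seen = {(r.peptide, r.allele) for r in results}
    expected = {(p, a) for p in unique for a in alleles}
    if seen != expected or len(results) != len(expected):
        raise ExternalBackendError(
            f"incomplete or duplicated result matrix: got {len(results)} results "
            f"for {len(expected)} pairs"
        )
    return results


def classify_binding(
    results: Iterable[BindingResult],
    strong_nm: float = STRONG_NM,
    non_binder_nm: float = NON_BINDER_NM,
) -> dict[tuple[str, str], str]:
    """Label each (peptide, allele) strong / weak / non-binder.

    Strong: affinity < ``strong_nm``; non-binder: affinity > ``non_binder_nm``;
    weak otherwise.  Both boundaries are exclusive of their threshold value.
    """
    if not (0 < strong_nm < non_binder_nm):
        raise ValueError("require 0 < strong_nm < non_binder_nm")
    labels = {}
    for r in results:
        if r.affinity_nm < strong_nm:
            label = "strong"
        elif r.affinity_nm > non_binder_nm:
            label = "non-binder"
        else:
            label = "weak"
        labels[(r.peptide, r.allele)] = label
    return labels


def write_binding_tsv(results: Sequence[BindingResult], path) -> None:
    with open(path, "w") as fh:
        fh.write("peptide\tallele\taffinity_nm\tpercentile_rank\n")
        for r in sorted(results, key=lambda r: (r.peptide, r.allele)):
            # repr round-trips floats exactly
            rank = "NA" if r.percentile_rank is None else repr(r.percentile_rank)
            fh.write(f"{r.peptide}\t{r.allele}\t{r.affinity_nm!r}\t{rank}\n")


def read_binding_tsv(path) -> list[BindingResult]:
    """Inverse of :func:`write_binding_tsv` (exact round-trip of the columns)."""
    results = []
    with open(path) as fh:
        header = fh.readline()
        for line in fh:
            pep, allele, aff, rank = line.rstrip("\n").split("\t")
            results.append(
                BindingResult(
                    pep, allele, float(aff), None if rank == "NA" else float(rank)
                )
            )
    return results
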