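"""Genome build description: ordered chromosomes with lengths.

Coordinates are 0-based, half-open everywhere inside the package (the BED
convention); 1-based positions appear only at VCF/report boundaries.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field


def chrom_sort_key(name: str) -> tuple[int, int, str]:
    """Natural ordering key for chromosome names.

    Numeric chromosomes sort numerically, then X, Y, M(T), then anything
    else lexicographically. A leading ``chr`` prefix is ignored.
    """
    base = name[3:] if name.lower().startswith("chr") else name
    if re.fullmatch(r"\d+", base):
        return (0, int(base), "")
    special = {"X": 1, "Y": 2, "M": 3, "MT": 3}
    if base.upper() in special:
        return (1, special[base.upper()], "")
    return (2, 0, base)


def is_sex_chrom(name: str) -> bool:
    base = name[3:] if name.lower().startswith("chr") else name
    return base.upper() in ("X", "Y")


@dataclass(frozen=True)
class GenomeBuild:
    """An ordered list of ``(name, length_bp)`` chromosomes.

    The order is fixed at construction and defines the global bin order used
    by the CNV pipeline; it is never re-sorted implicitly.
    """

    chromosomes: tuple[tuple[str, int], ...]
    _index: dict[str, int] = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        if not self.chromosomes:
            raise ValueError("build must contain at least one chromosome")
        names = [name for name, _ in self.chromosomes]
        if len(set(names)) != len(names):
            raise ValueError("chromosome names must be unique")
        for name, length in self.chromosomes:
            if length <= 0:
                raise ValueError(f"chromosome {name!r} has non-positive length {length}")
        object.__setattr__(self, "chromosomes", tuple((str(n), int(l)) for n, l in self.chromosomes))
        object.__setattr__(self, "_index", {n: i for i, (n, _) in enumerate(self.chromosomes)})

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(n for n, _ in self.chromosomes)

    def __contains__(self, name: str) -> bool:
        return name in self._index

    def __len__(self) -> int:
        return len(self.chromosomes)

    def length_of(self, name: str) -> int:
        try:
            return self.chromosomes[self._index[name]][1]
        except KeyError:
            raise KeyError(f"unknown chromosome {name!r}") from None

    @property
    def total_length(self) -> int:
        return sum(l for _, l in self.chromosomes)

    @classmethod
    def from_chrom_sizes(cls, path) -> "GenomeBuild":
        """Read a two-column ``chrom.sizes`` TSV (name, length)."""
        chroms = []
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                fields = line.split("\t")
                if len(fields) < 2:
                    raise ValueError(f"malformed chrom.sizes line: {line!r}")
                chroms.append((fields[0], int(fields[1])))
        return cls(tuple(chroms))

    def to_chrom_sizes(self, path) -> None:
        with open(path, "w") as fh:
            for name, length in self.chromosomes:
                fh.write(f"{name}\t{length}\n")
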