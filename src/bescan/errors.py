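"""Exception hierarchy shared by every bescan module."""


class BescanError(Exception):
    """Base class for all package errors."""


class AlphabetError(BescanError):
    """A sequence contains a character outside the IUPAC DNA alphabet."""

    def __init__(self, symbol: str, offset: int, name: str = ""):
        self.symbol = symbol
        self.offset = offset
        where = f" in '{name}'" if name else ""
        super().__init__(
            f"non-IUPAC symbol {symbol!r} at offset {offset}{where}"
        )


class CoordinateError(BescanError):
    """A genomic coordinate falls outside its contig."""

    def __init__(self, chrom: str, pos: int, contig_length: int, detail: str = ""):
        self.chrom = chrom
        self.pos = pos
        self.contig_length = contig_length
        msg = f"position {pos} outside contig {chrom!r} (length {contig_length})"
        if detail:
            msg += f": {detail}"
        super().__init__(msg)


class FormatError(BescanError):
    """An input file violates its declared format."""


class ContractError(BescanError):
    """A caller violated a documented precondition."""


class ReferenceMismatchError(BescanError):
    """A variant's REF allele disagrees with the genome at its position.

    Raised as a hard stop: it almost always signals a coordinate-convention
    bug (0- vs 1-based) or a genome/variant-table build mismatch.
    """

    def __init__(self, chrom: str, pos: int, expected: str, found: str):
        self.chrom = chrom
        self.pos = pos
        super().__init__(
            f"variant REF {expected!r} at {chrom}:{pos} disagrees with "
            f"genome base {found!r}"
        )
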