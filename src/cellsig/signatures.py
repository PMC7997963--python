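"""Gene signatures: named gene sets with optional up/down direction split."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from .exceptions import ConfigError

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class GeneSignature:
    """A named gene set, optionally split into up- and down-regulated members.

    ``up_genes`` and ``down_genes`` must be disjoint and their union nonempty.
    A purely unsigned signature puts all members in ``up_genes``.
    """

    name: str
    up_genes: tuple[str, ...] = ()
    down_genes: tuple[str, ...] = ()

    def __post_init__(self):
        up = tuple(dict.fromkeys(self.up_genes))
        down = tuple(dict.fromkeys(self.down_genes))
        object.__setattr__(self, "up_genes", up)
        object.__setattr__(self, "down_genes", down)
        if not up and not down:
            raise ConfigError(f"signature '{self.name}' has no member genes")
        overlap = set(up) & set(down)
        if overlap:
            raise ConfigError(
                f"signature '{self.name}' lists genes in both directions: "
                f"{sorted(overlap)}"
            )

    @property
    def members(self) -> tuple[str, ...]:
        return self.up_genes + self.down_genes

    def resolve(self, gene_universe) -> "ResolvedSignature":
        """Intersect the signature with a gene universe.

        Unresolvable members are reported via a warning and dropped, so the
        effective signature size N stays honest. Raises if nothing resolves.
        """
        universe = set(gene_universe)
        up = tuple(g for g in self.up_genes if g in universe)
        down = tuple(g for g in self.down_genes if g in universe)
        missing = [g for g in self.members if g not in universe]
        if missing:
            logger.warning(
                "signature '%s': %d/%d member genes absent from the matrix "
                "and dropped: %s",
                self.name, len(missing), len(self.members), missing[:10],
            )
        if not up and not down:
            raise ConfigError(
                f"no gene of signature '{self.name}' is present in the matrix"
            )
        return ResolvedSignature(
            signature=GeneSignature(self.name, up, down), missing=tuple(missing)
        )


@dataclass(frozen=True)
class ResolvedSignature:
    """A signature restricted to a matrix's gene universe."""

    signature: GeneSignature
    missing: tuple[str, ...] = field(default=())

    @property
    def name(self) -> str:
        return self.signature.name

    @property
    def up_genes(self) -> tuple[str, ...]:
        return self.signature.up_genes

    @property
    def down_genes(self) -> tuple[str, ...]:
        return self.signature.down_genes
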