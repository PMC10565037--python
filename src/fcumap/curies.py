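"""CURIE prefix maps: expansion and contraction of compact IRIs.

Ids are treated as opaque strings; expansion is pure concatenation of the
prefix binding and the local part, contraction inverts it (longest binding
wins). When a binding has no trailing separator and the local part no leading
one, a ``/`` joiner is inserted — bindings like
``http://taxref.mnhn.fr/lod/taxref-ld`` pair with local parts like
``taxon/94503``. The joiner is configurable per prefix.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

from .errors import UnknownPrefixError

logger = logging.getLogger(__name__)

#: Default bindings for the two aligned knowledge graphs and the mapping
#: vocabulary itself.
DEFAULT_BINDINGS = {
    "fcu": "http://ontology.inrae.fr/frenchcropusage",
    "taxref": "http://taxref.mnhn.fr/lod/taxref-ld",
    "ontofcu": "http://ontology.inrae.fr/frenchcropusage/def",
    "semapv": "https://w3id.org/semapv/vocab",
}

_SEPARATORS = ("/", "#", ":")


@dataclass
class CurieMap:
    """An ordered prefix → IRI-prefix map."""

    bindings: dict[str, str] = field(default_factory=dict)
    #: optional per-prefix joiner overriding the default heuristic
    joiners: dict[str, str] = field(default_factory=dict)

    @classmethod
    def default(cls) -> "CurieMap":
        return cls(bindings=dict(DEFAULT_BINDINGS))

    def _joiner(self, prefix: str, local: str) -> str:
        if prefix in self.joiners:
            return self.joiners[prefix]
        binding = self.bindings[prefix]
        if binding.endswith(_SEPARATORS) or local.startswith(_SEPARATORS):
            return ""
        return "/"

    def is_curie(self, identifier: str) -> bool:
        """True when *identifier* looks like prefix:local rather than a full IRI."""
        if "://" in identifier:
            return False
        prefix, sep, _ = identifier.partition(":")
        return bool(sep) and bool(prefix)

    def expand(self, curie: str) -> str:
        """Expand ``prefix:local`` to a full IRI.

        Full IRIs pass through unchanged; an unbound prefix raises
        :class:`UnknownPrefixError`.
        """
        if not self.is_curie(curie):
            return curie
        prefix, _, local = curie.partition(":")
        if prefix not in self.bindings:
            raise UnknownPrefixError(f"no binding for CURIE prefix {prefix!r}")
        return self.bindings[prefix] + self._joiner(prefix, local) + local

    def contract(self, iri: str) -> str:
        """Contract a full IRI to a CURIE using the longest matching binding.

        If nothing matches the IRI is returned unchanged with a warning.
        """
        best: tuple[str, str] | None = None
        for prefix, binding in self.bindings.items():
            stem = binding + self._joiner(prefix, "x")[:1]
            for candidate in (stem, binding):
                if iri.startswith(candidate) and len(iri) > len(candidate):
                    if best is None or len(candidate) > len(best[1]):
                        best = (prefix, candidate)
        if best is None:
            warnings.warn(f"no CURIE binding matches {iri!r}; keeping as-is", stacklevel=2)
            return iri
        prefix, stem = best
        return f"{prefix}:{iri[len(stem):]}"

    def merged_with(self, other: "CurieMap") -> "CurieMap":
        """Union of two maps; conflicting bindings for a prefix are an error."""
        from .errors import MergeError

        merged = dict(self.bindings)
        for prefix, binding in other.bindings.items():
            if prefix in merged and merged[prefix] != binding:
                raise MergeError(
                    f"prefix {prefix!r} bound to both {merged[prefix]!r} and {binding!r}"
                )
            merged[prefix] = binding
        return CurieMap(bindings=merged, joiners={**self.joiners, **other.joiners})
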