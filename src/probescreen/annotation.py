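"""Local gene-ontology keyword filtering over a probe-set annotation table.

A reproducible stand-in for interactive web annotation queries: the
annotation source is a pinned local table (probe-set id → GO term strings),
and candidate probe sets are filtered by a keyword (default ``'GTP'``,
matching terms such as 'GTP binding', 'GTPase activity', 'GTPase activator
activity', 'small GTPase regulator activity' and 'small GTPase mediated
signal transduction').
"""

from __future__ import annotations

import re

__all__ = ["AnnotationTable", "load_annotations", "keyword_filter", "write_annotations"]


class AnnotationTable:
    """Mapping probe-set id → set of GO term strings.

    A probe set may carry zero terms (it is then simply absent from the
    mapping). ``tagged_ids`` optionally records which sets the simulator
    tagged with a keyword term.
    """

    def __init__(self, terms: dict | None = None, tagged_ids=None):
        self._terms: dict = {}
        for probeset_id, term_set in (terms or {}).items():
            self._terms[probeset_id] = {str(t) for t in term_set}
            if any(not t for t in self._terms[probeset_id]):
                raise ValueError(f"empty term string for probe set {probeset_id!r}")
        self.tagged_ids = list(tagged_ids) if tagged_ids is not None else None

    def get(self, probeset_id) -> set:
        return self._terms.get(probeset_id, set())

    def add(self, probeset_id, term: str) -> None:
        if not term:
            raise ValueError(f"empty term string for probe set {probeset_id!r}")
        self._terms.setdefault(probeset_id, set()).add(term)

    def __contains__(self, probeset_id) -> bool:
        return probeset_id in self._terms

    def __len__(self) -> int:
        return len(self._terms)

    def ids(self):
        return list(self._terms)

    def items(self):
        return self._terms.items()


def load_annotations(path, format: str = "two_column_tsv", term_names: dict | None = None) -> AnnotationTable:
    """Load an annotation table.

    ``two_column_tsv``: one tab-separated ``(probeset_id, term)`` pair per
    line; lines starting with ``#`` (and a 'probeset_id' header, if present)
    are skipped. ``gaf_like``: columns 2 and 5 of a GAF 2-style file are the
    (object id, term id) pair; ``term_names`` optionally maps term ids to
    readable names. Duplicate pairs are deduplicated silently; malformed
    lines raise with their line number.
    """
    if format not in ("two_column_tsv", "gaf_like"):
        raise ValueError(f"unknown annotation format {format!r}")
    table = AnnotationTable()
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "!")):
                continue
            fields = line.split("\t")
            if format == "two_column_tsv":
                if lineno == 1 and fields[0] == "probeset_id":
                    continue
                if len(fields) < 2 or not fields[0] or not fields[1]:
                    raise ValueError(f"{path}:{lineno}: expected 'probeset_id<TAB>term', got {line!r}")
                probeset_id, term = fields[0], fields[1]
            else:  # gaf_like
                if len(fields) < 5 or not fields[1] or not fields[4]:
                    raise ValueError(f"{path}:{lineno}: expected >=5 GAF columns with id in col 2 "
                                     f"and term in col 5, got {line!r}")
                probeset_id, term = fields[1], fields[4]
                if term_names:
                    term = term_names.get(term, term)
            table.add(probeset_id, term)
    return table


def write_annotations(table: AnnotationTable, path) -> None:
    with open(path, "w") as handle:
        handle.write("probeset_id\tterm\n")
        for probeset_id in table.ids():
            for term in sorted(table.get(probeset_id)):
                handle.write(f"{probeset_id}\t{term}\n")


def keyword_filter(
    table: AnnotationTable,
    ids,
    keyword: str = "GTP",
    match: str = "substring",
    ignore_case: bool = False,
) -> list:
    """Return the candidate ids annotated with ≥1 term matching ``keyword``.

    ``substring`` (default) is a plain case-sensitive substring test —
    'GTP' matches 'GTPase activity' but not 'ATP binding'; ``word`` requires
    the keyword as a whole word. Input order is preserved; ids absent from
    the table simply do not match. The result is always a subset of ``ids``
    and the operation is idempotent.
    """
    if not keyword:
        raise ValueError("keyword must be non-empty")
    if match not in ("substring", "word"):
        raise ValueError(f"unknown match mode {match!r}")

    if match == "word":
        pattern = re.compile(rf"\b{re.escape(keyword)}\b", re.IGNORECASE if ignore_case else 0)
        hit = pattern.search
    else:
        needle = keyword.lower() if ignore_case else keyword

        def hit(term, _needle=needle):
            hay = term.lower() if ignore_case else term
            return _needle in hay

    return [i for i in ids if any(hit(term) for term in table.get(i))]
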