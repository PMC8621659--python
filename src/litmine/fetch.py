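"""Optional live retrieval from PubMed via the NCBI E-utilities API.

Network-only convenience; nothing in the package or its tests depends on it.
Each query clause (default: the shipped clause list) is issued as a separate
esearch; PMID sets are unioned (duplicate counts logged) and records fetched
with efetch in MEDLINE format, parsed with Bio.Medline. Uses stdlib urllib.
"""

from __future__ import annotations

import io
import logging
import time
import urllib.parse
import urllib.request
from importlib import resources

import yaml

from .corpus import Article

logger = logging.getLogger(__name__)

EUTILS = "https://eutils.ncbi.nlm.nih.gov/entrez/eutils"


def default_queries() -> list[str]:
    text = resources.files("litmine.data").joinpath("model1_queries.yaml").read_text()
    return yaml.safe_load(text)["queries"]


def _get(url: str, params: dict) -> str:
    full = f"{url}?{urllib.parse.urlencode(params)}"
    with urllib.request.urlopen(full, timeout=60) as resp:
        return resp.read().decode("utf-8", errors="replace")


def esearch(query: str, email: str, retmax: int = 10000) -> list[str]:
    text = _get(
        f"{EUTILS}/esearch.fcgi",
        {"db": "pubmed", "term": query, "retmax": retmax, "email": email},
    )
    import re

    return re.findall(r"<Id>(\d+)</Id>", text)


def efetch_medline(pmids: list[str], email: str, chunk: int = 200) -> list[Article]:
    from Bio import Medline

    articles = []
    for i in range(0, len(pmids), chunk):
        text = _get(
            f"{EUTILS}/efetch.fcgi",
            {
                "db": "pubmed",
                "id": ",".join(pmids[i : i + chunk]),
                "rettype": "medline",
                "retmode": "text",
                "email": email,
            },
        )
        for rec in Medline.parse(io.StringIO(text)):
            pmid = rec.get("PMID")
            if pmid:
                articles.append(
                    Article(id=pmid, title=rec.get("TI", "") or "",
                            abstract=rec.get("AB", "") or "")
                )
        time.sleep(0.4)  # E-utilities rate limit without an API key
    return articles


def fetch_records(
    queries: list[str] | None = None, email: str = "", retmax: int = 10000
) -> list[Article]:
    """Union of all query clauses' results, deduplicated by PMID."""
    queries = queries or default_queries()
    seen: dict[str, None] = {}
    n_dup = 0
    for q in queries:
        ids = esearch(q, email, retmax)
        logger.info("esearch %r -> %d ids", q[:60], len(ids))
        for pmid in ids:
            if pmid in seen:
                n_dup += 1
            else:
                seen[pmid] = None
        time.sleep(0.4)
    logger.info("union %d unique PMIDs (%d duplicates across clauses)", len(seen), n_dup)
    return efetch_medline(list(seen), email)
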