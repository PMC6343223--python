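"""Download a PDB entry from the wwPDB archive.

The endpoint is a URL template with an ``{id}`` placeholder, configurable via
the ``PDBTK_FETCH_URL`` environment variable (default: the RCSB download
service, gzip-compressed).  Responses are transparently decompressed when
they carry the gzip magic, so both plain and compressed endpoints work —
including ``file://`` URLs, which is how the test suite exercises the tool
without a network.
"""

from __future__ import annotations

import gzip
import os
import re
import urllib.error
import urllib.request

from .records import PDBError

__all__ = ["FetchError", "fetch_entry", "DEFAULT_URL_TEMPLATE"]

DEFAULT_URL_TEMPLATE = "https://files.rcsb.org/download/{id}.pdb.gz"
ENV_VAR = "PDBTK_FETCH_URL"

_ID_RE = re.compile(r"^[0-9][A-Za-z0-9]{3}$")


class FetchError(PDBError):
    """Malformed accession, HTTP failure, or unreachable endpoint."""


def fetch_entry(pdb_id: str, url_template: str | None = None, timeout: float = 30.0) -> str:
    """Return the PDB-format text of an entry by 4-character accession."""
    if not _ID_RE.match(pdb_id):
        raise FetchError(
            f"invalid PDB accession {pdb_id!r}: expected a digit followed by "
            "three alphanumeric characters (e.g. 1ctf)")
    template = url_template or os.environ.get(ENV_VAR) or DEFAULT_URL_TEMPLATE
    url = template.format(id=pdb_id.lower())
    try:
        with urllib.request.urlopen(url, timeout=timeout) as resp:
            payload = resp.read()
    except urllib.error.HTTPError as exc:
        raise FetchError(f"entry {pdb_id!r} not retrievable: HTTP {exc.code} "
                         f"{exc.reason}") from exc
    except (urllib.error.URLError, OSError) as exc:
        raise FetchError(f"could not reach {url}: {exc}") from exc
    if payload[:2] == b"\x1f\x8b":
        payload = gzip.decompress(payload)
    return payload.decode("ascii", errors="replace")
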