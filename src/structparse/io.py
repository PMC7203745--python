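"""Top-level reading API: file-type detection, the open/fetch pipeline.

Parsing always follows the same five steps whatever the source: get the
content (filesystem or HTTP), detect the format, parse to the
format-specific dictionary, standardize to the shared data dictionary,
then build the File object hierarchy.
"""

import gzip
import logging
from pathlib import Path

from .pdb import parse_pdb_string
from .mmcif import parse_mmcif_string
from .mmtf import decode_mmtf
from .standardize import standardize
from .build import build_file

logger = logging.getLogger(__name__)

#: URL templates for remote fetching, overridable by callers/config.
FETCH_URLS = {
    "cif": "https://files.rcsb.org/download/{code}.cif",
    "pdb": "https://files.rcsb.org/download/{code}.pdb",
    "mmtf": "https://mmtf.rcsb.org/v1.0/full/{code}",
}

_MSGPACK_MAP_MARKERS = set(range(0x80, 0x90)) | {0xDE, 0xDF}


class NotFoundError(Exception):
    """The requested entry or path does not exist."""


def detect_filetype(filename, content):
    """Classify content as ``pdb``, ``cif`` or ``mmtf``.

    The file extension decides when recognizable (.pdb/.ent, .cif/.mmcif,
    .mmtf, optionally .gz-suffixed); otherwise the content is sniffed: a
    leading msgpack map marker means MMTF, a line starting ``data_`` or
    ``loop_`` (or an item starting ``_``) means mmCIF, and decodable text
    falls back to PDB.
    """
    name = (filename or "").lower()
    if name.endswith(".gz"):
        name = name[:-3]
    for suffixes, filetype in (((".pdb", ".ent"), "pdb"),
                               ((".cif", ".mmcif"), "cif"),
                               ((".mmtf",), "mmtf")):
        if name.endswith(suffixes):
            return filetype
    if isinstance(content, bytes):
        if content and content[0] in _MSGPACK_MAP_MARKERS:
            return "mmtf"
        try:
            content = content.decode("utf-8")
        except UnicodeDecodeError:
            raise ValueError(f"Cannot determine the file type of "
                             f"{filename!r}: undecodable content with no "
                             f"recognized extension") from None
    for line in content.split("\n"):
        stripped = line.strip()
        if not stripped or stripped.startswith("#"):
            continue
        if stripped.startswith(("data_", "loop_", "_")):
            return "cif"
        break
    return "pdb"


def parse_filestring(content, filetype):
    """Content → file-specific dictionary for the given format."""
    if filetype == "mmtf":
        return decode_mmtf(content)
    if isinstance(content, bytes):
        content = content.decode("utf-8")
    if filetype == "cif":
        return parse_mmcif_string(content)
    if filetype == "pdb":
        return parse_pdb_string(content)
    raise ValueError(f"Unknown file type {filetype!r}")


def read_string(content, filetype=None, filename=""):
    """Run the full pipeline on in-memory content, returning a File."""
    if filetype is None:
        filetype = detect_filetype(filename, content)
    raw = parse_filestring(content, filetype)
    data = standardize(raw, filetype)
    return build_file(data, source_format=filetype)


def open_local(path, filetype=None):
    """Open a structure file from disk (gzip decompressed transparently)."""
    path = Path(path)
    content = path.read_bytes()
    if content[:2] == b"\x1f\x8b":
        content = gzip.decompress(content)
    return read_string(content, filetype=filetype, filename=path.name)


def fetch_remote(code, filetype="cif", transport=None):
    """Download an entry by accession code over HTTP and parse it.

    ``transport`` is a callable url -> bytes (injected in tests); the
    default uses requests. A 404 raises NotFoundError; other transport
    failures propagate as IOError.
    """
    url = FETCH_URLS[filetype].format(code=code)
    if transport is None:
        transport = _http_get
    content = transport(url)
    file = read_string(content, filetype=filetype, filename=f"{code}.{filetype}")
    if file.code is None:
        file.code = code
    return file


def _http_get(url):
    import requests
    try:
        response = requests.get(url, timeout=30)
    except requests.RequestException as error:
        raise IOError(f"Transport failure fetching {url}: {error}") from error
    if response.status_code == 404:
        raise NotFoundError(f"No entry at {url}")
    if response.status_code != 200:
        raise IOError(f"HTTP {response.status_code} fetching {url}")
    return response.content


def fetch_ssh(host, path, **kwargs):
    """Fetching over SSH is declared but not implemented."""
    raise NotImplementedError(
        "SSH fetching is not implemented; use open_local or fetch_remote")


def save(file, path):
    """Write a File to ``path``, choosing the writer from the extension
    (.pdb, .cif, .mmtf or .json)."""
    from .writers import write_pdb, write_mmcif, write_mmtf, to_json
    from .build import structure_to_data_dict
    path = Path(path)
    suffix = path.suffix.lower()
    if suffix == ".pdb":
        path.write_text(write_pdb(file))
    elif suffix in (".cif", ".mmcif"):
        path.write_text(write_mmcif(file))
    elif suffix == ".mmtf":
        path.write_bytes(write_mmtf(file))
    elif suffix == ".json":
        path.write_text(to_json(structure_to_data_dict(file), indent=2))
    else:
        raise ValueError(f"Unsupported output extension {suffix!r}")
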