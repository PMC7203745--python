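"""mmCIF (CIF 1.1 syntax) parsing to the file-specific dictionary.

Every category — whether written as single ``_category.item value`` pairs
or as a ``loop_`` table — becomes a list of row mappings from column name
to string value. Values stay strings at this stage (``?`` and ``.``
included) so the raw view remains faithful to the source; typing happens
in the standardizer.

The tokenizer is the subtle part: quoted tokens may contain whitespace and
the opposite quote character, and a quote character is only a delimiter
when it is followed by whitespace or end-of-line — so ``'O5' epimer'`` is
one token, ``O5' epimer``. Semicolon-first-column lines open and close
multiline text blocks that are returned as a single token with newlines
preserved.
"""


def tokenize_mmcif_line(line):
    """Split one mmCIF line into tokens.

    Whitespace separates bare tokens; a single or double quote opens a
    quoted token only at a token boundary, and closes it only when
    followed by whitespace or end-of-line. A ``#`` at a token boundary
    starts a comment. Raises ValueError on a quote left open at
    end-of-line.
    """
    return [token for token, _ in _tokenize_flagged(line)]


def _token_stream(text):
    """Yield (token, is_value) pairs; quoted and multiline tokens are
    always values, bare tokens may be keywords."""
    multiline = None
    for line in text.split("\n"):
        line = line.rstrip("\r")
        if multiline is not None:
            if line.startswith(";"):
                yield "\n".join(multiline), True
                multiline = None
                rest = line[1:].strip()
                if rest:
                    for token in tokenize_mmcif_line(rest):
                        yield token, True
            else:
                multiline.append(line)
            continue
        if line.startswith(";"):
            first = line[1:]
            multiline = [first] if first else []
            continue
        stripped = line.strip()
        if not stripped or stripped.startswith("#"):
            continue
        # track quoting so quoted tokens are flagged as forced values
        for token, quoted in _tokenize_flagged(line):
            yield token, quoted
    if multiline is not None:
        raise ValueError("Unterminated multiline (;) block")


def _tokenize_flagged(line):
    tokens = []
    i, n = 0, len(line)
    while i < n:
        c = line[i]
        if c.isspace():
            i += 1
            continue
        if c == "#":
            break
        if c in "'\"":
            quote = c
            i += 1
            start = i
            while True:
                if i >= n:
                    raise ValueError(f"Unterminated {quote} quote: {line!r}")
                if line[i] == quote and (i + 1 == n or line[i + 1].isspace()):
                    break
                i += 1
            tokens.append((line[start:i], True))
            i += 1
        else:
            start = i
            while i < n and not line[i].isspace():
                i += 1
            tokens.append((line[start:i], False))
    return tokens


def _split_item(name):
    name = name[1:]  # leading underscore
    if "." in name:
        category, column = name.split(".", 1)
    else:
        category, column = name, name
    return category, column


def parse_mmcif_string(text):
    """Parse a CIF filestring into {category: [row mapping, ...]}.

    The first ``data_`` block is read (leading comments allowed). A
    ``loop_`` whose value count is not a multiple of its header count
    raises ValueError.
    """
    tokens = list(_token_stream(text))
    mmcif = {}
    i, n = 0, len(tokens)
    while i < n:
        token, is_value = tokens[i]
        if not is_value and token.lower().startswith("data_"):
            mmcif.setdefault("__block__", token[5:])
            i += 1
        elif not is_value and token.lower() == "loop_":
            i += 1
            headers = []
            while i < n and not tokens[i][1] and tokens[i][0].startswith("_"):
                headers.append(_split_item(tokens[i][0]))
                i += 1
            if not headers:
                raise ValueError("loop_ with no item names")
            values = []
            while i < n and (tokens[i][1] or not (
                    tokens[i][0].startswith("_")
                    or tokens[i][0].lower() in ("loop_",)
                    or tokens[i][0].lower().startswith("data_"))):
                values.append(tokens[i][0])
                i += 1
            if len(values) % len(headers):
                raise ValueError(
                    f"loop_ over {headers[0][0]}: {len(values)} values is "
                    f"not a multiple of {len(headers)} columns")
            category = headers[0][0]
            rows = mmcif.setdefault(category, [])
            for j in range(0, len(values), len(headers)):
                rows.append({column: values[j + k]
                             for k, (_, column) in enumerate(headers)})
        elif not is_value and token.startswith("_"):
            category, column = _split_item(token)
            if i + 1 >= n:
                raise ValueError(f"Item {token} has no value")
            value = tokens[i + 1][0]
            rows = mmcif.setdefault(category, [{}])
            rows[0][column] = value
            i += 2
        else:
            raise ValueError(f"Unexpected token {token!r} outside any item")
    mmcif.pop("__block__", None)
    return mmcif
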