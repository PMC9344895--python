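import pytest

# printed one-decimal coefficient triples for each built-in parameter row
TABLE_COEFFS = {
    ("C", "G", 89): (-0.9, -1.8, -1.7),
    ("G", "C", 89): (-0.9, -1.2, -1.7),
    ("C", "G", 99): (2.3, 1.3, -0.4),
    ("G", "C", 99): (2.2, 1.9, -0.4),
    ("C", "G", 4): (-2.8, -3.0, 0.9),
    ("G", "C", 4): (-2.8, -2.2, 0.9),
}


@pytest.fixture(scope="session")
def table_coefficient_pairs():
    """The six built-in (alpha, beta) pairs, at printed precision."""
    return sorted({(a, b) for a, b, _ in TABLE_COEFFS.values()})


def naive_enumerate_paths(m: int) -> list[str]:
    """Independent oracle: filter all 4^m strings by a direct validity scan."""
    from itertools import product

    out = []
    for tup in product("DHIU", repeat=m):
        height = 0
        ok = True
        for ch in tup:
            if ch == "U":
                height += 1
            elif ch == "D":
                height -= 1
                if height < 0:
                    ok = False
                    break
        if ok and height == 0:
            out.append("".join(tup))
    return out
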