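import pytest

from arbamp import amplicon_prediction as ap

# The four published short priming targets used as the default test cocktail.
COCKTAIL_TARGETS = ["GTCGCCC", "TTTGATC", "TTTATGT", "TTTTTGT"]
ADAPTER_F = "CGCTCTTCCGATCT"
ADAPTER_R = "TGCTCTTCCGATCT"


@pytest.fixture(scope="session")
def cocktail():
    constructs = []
    for i, target in enumerate(COCKTAIL_TARGETS):
        constructs.append(
            ap.PrimerConstruct(name=f"p{i}-f", adapter=ADAPTER_F, target=target)
        )
        constructs.append(
            ap.PrimerConstruct(name=f"p{i}-r", adapter=ADAPTER_R, target=target)
        )
    return ap.CocktailSpec(constructs=tuple(constructs))


@pytest.fixture
def cocktail_tsv(tmp_path):
    path = tmp_path / "cocktail.tsv"
    lines = ["name\tadapter\tspacer_len\ttarget"]
    for i, target in enumerate(COCKTAIL_TARGETS):
        lines.append(f"p{i}-f\t{ADAPTER_F}\t7\t{target}")
        lines.append(f"p{i}-r\t{ADAPTER_R}\t7\t{target}")
    path.write_text("\n".join(lines) + "\n")
    return path
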