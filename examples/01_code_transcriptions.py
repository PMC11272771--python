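"""Code a handful of free-text listener transcriptions into phoneme slots.

Shows the rule pipeline: spelling normalization, syllabification, cluster
and diphthong handling, real-word exclusion, and the strict vs relabeled
treatment of responses with extra noise syllables.
"""

from apephon import CodingScheme, RawTranscription, code

responses = ["Ma-Ma!", "mamma", "wama", "fnaya", "my house", "Homo-mo", "Ash-ma-ma"]
lexicon = frozenset({"my house"})

for variant in ("strict", "relabeled"):
    scheme = CodingScheme(variant=variant, real_word_lexicon=lexicon)
    print(f"\n{variant} scheme:")
    for text in responses:
        r = code(RawTranscription("L1", "demo", text), scheme)
        if r.na_reason != "none":
            print(f"  {text!r:14} -> n/a ({r.na_reason})")
        else:
            flag = "  [relabeled]" if r.relabeled else ""
            print(f"  {text!r:14} -> /{r.c1}{r.v1}{r.c2}{r.v2}/{flag}")

print("\nSlots are (C1, V1, C2, V2); n/a responses are excluded from agreement")
print("denominators under the without-n/a convention.")
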