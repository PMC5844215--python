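"""Demonym / population-label lexicon for nationality-entity tagging.

The lexicon drives the NORP (nationalities, religious or political groups)
entity category of the heuristic linguistic backend.  It intentionally mixes
country demonyms with population and ethnicity labels common in genetic
epidemiology (e.g. "Han", "Caucasian", "Ashkenazi"), since abstracts use
both interchangeably when describing study cohorts.
"""

from __future__ import annotations

# Single-token labels, matched case-insensitively against capitalized tokens;
# plural surface forms ("Europeans") are reduced before lookup.
NATIONALITY_LEXICON: frozenset[str] = frozenset(
    s.lower()
    for s in (
        # broad ancestry / population labels
        "African", "American", "Asian", "Caucasian", "European", "Hispanic",
        "Latino", "Amerindian", "Aboriginal", "Oceanian", "Mediterranean",
        # East / Southeast / South Asia
        "Chinese", "Han", "Japanese", "Korean", "Taiwanese", "Mongolian",
        "Tibetan", "Uyghur", "Thai", "Vietnamese", "Filipino", "Indonesian",
        "Malay", "Malaysian", "Singaporean", "Burmese", "Cambodian", "Lao",
        "Hmong", "Indian", "Pakistani", "Bangladeshi", "Nepali", "Sinhalese",
        "Tamil", "Afghan",
        # Middle East / Central Asia
        "Arab", "Arabian", "Jewish", "Ashkenazi", "Sephardi", "Israeli",
        "Persian", "Iranian", "Iraqi", "Turkish", "Kurdish", "Lebanese",
        "Syrian", "Jordanian", "Saudi", "Emirati", "Kuwaiti", "Qatari",
        "Yemeni", "Omani", "Uzbek", "Kazakh", "Tajik", "Turkmen", "Azeri",
        "Armenian", "Georgian",
        # Europe
        "Finnish", "Swedish", "Danish", "Norwegian", "Icelandic", "Estonian",
        "Latvian", "Lithuanian", "British", "English", "Scottish", "Welsh",
        "Irish", "French", "German", "Dutch", "Belgian", "Swiss", "Austrian",
        "Italian", "Sicilian", "Sardinian", "Spanish", "Basque", "Catalan",
        "Portuguese", "Greek", "Polish", "Czech", "Slovak", "Hungarian",
        "Romanian", "Bulgarian", "Serbian", "Croatian", "Bosnian",
        "Slovenian", "Macedonian", "Albanian", "Russian", "Ukrainian",
        "Belarusian", "Moldovan", "Roma",
        # Africa
        "Egyptian", "Moroccan", "Algerian", "Tunisian", "Libyan", "Berber",
        "Nigerian", "Ghanaian", "Senegalese", "Malian", "Ethiopian",
        "Eritrean", "Somali", "Kenyan", "Ugandan", "Tanzanian", "Sudanese",
        "Zulu", "Xhosa", "Yoruba", "Igbo", "Bantu", "Malagasy",
        # Americas / Oceania
        "Canadian", "Mexican", "Guatemalan", "Cuban", "Haitian", "Jamaican",
        "Brazilian", "Argentine", "Argentinian", "Chilean", "Peruvian",
        "Bolivian", "Colombian", "Venezuelan", "Ecuadorian", "Uruguayan",
        "Paraguayan", "Inuit", "Amish", "Australian", "Maori", "Samoan",
        "Tongan", "Fijian", "Hawaiian",
    )
)


def is_nationality_token(token_text: str) -> bool:
    """True when a capitalized token is a nationality/population label.

    Capitalization is required so that common-noun homographs ("turkey",
    "polish") are not tagged mid-sentence.
    """
    if not token_text or not token_text[0].isupper():
        return False
    low = token_text.lower()
    if low in NATIONALITY_LEXICON:
        return True
    # plural demonyms: "Europeans", "Finns" are left out; strip a plain -s
    if low.endswith("s") and low[:-1] in NATIONALITY_LEXICON:
        return True
    return False
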