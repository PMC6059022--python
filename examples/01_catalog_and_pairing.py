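"""Enumerate the integrin heterodimer repertoire from the packaged catalog.

The 27 integrin genes (18 α, 9 β chains) assemble into exactly 24 receptors
under fixed pairing rules; β4 pairs only with α6, and ITGBL1 has no known
partner.
"""

from dimertarget import enumerate_heterodimers, load_catalog, load_pairing_rules, partners_of

catalog = load_catalog()
rules = load_pairing_rules(catalog=catalog)

print(f"{len(catalog)} genes: {len(catalog.alpha_genes)} alpha, {len(catalog.beta_genes)} beta")
dimers = enumerate_heterodimers(catalog, rules)
print(f"{len(dimers)} heterodimers:", ", ".join(d.display for d in dimers))
for gene in ("ITGAV", "ITGB4", "ITGBL1"):
    print(f"partners of {gene}: {sorted(partners_of(gene, rules, catalog)) or 'none'}")
# αv is the hub alpha chain (5 receptors); ITGBL1's empty set means it can
# never appear in a heterodimer call.
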