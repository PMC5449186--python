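>SOD1_HUMAN offset=1 human Cu/Zn superoxide dismutase, mature chain (initiator Met removed; UniProt P00441)
ATKAVCVLKGDGPVQGIINFEQKESNGPVKVWGSIKGLTEGLHGFHVHEFGDNTAGCTSA
GPHFNPLSRKHGGPKDEERHVGDLGNVTADKDGVADVSIEDSVISLSGDHCIIGRTLVVH
EKADDLGKGGNEESTKTGNAGSRLACGVIGIAQ
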