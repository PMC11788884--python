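(trichoplax,(sea_anemone,((((c_elegans,c_briggsae),(mosquito,fruit_fly)),limpet),(sea_urchin,(amphioxus,(ascidian,(((arctic_lamprey,sea_lamprey),(hagfish,brown_hagfish)),(ghost_shark,((zebrafish,fugu),(frog,(chicken,(human,(mouse,rat)))))))))))));
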