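>design_01 IgE FG-loop display design on the 1YN3 EAP scaffold
GVHVPFTVTHPHLPRALSSHLQFNKDQEILFEQLAKKVMRVLKEQLGIDEEEARRAKQVSFIVYFKDGSSTKIDGSSDEHEENKINAAEIKKIEVKVD
>design_02 IgE FG-loop display design on the 1YN3 EAP scaffold
GVQVPFTVTHPHLPRALSSHLTFNKDQEILYEELAKKVMRVLEEQLGITEEEARRAKQVKFVVYFKDGSSTEIDGSSDEHEENKINAAEIKKIEVKVD
>design_03 IgE FG-loop display design on the 1YN3 EAP scaffold
GVQVPYTVTHPHLPRALSSHLTFNKDQEILYEQLAKKVMKVAEEKLGITEEEARRAKQFKFVVYFKDGSSTEIDGKSDEHEENKINAAEIKKIEVKID
>design_04 IgE FG-loop display design on the 1YN3 EAP scaffold
GVTVPYTVTHPHLPRALSSHLTFNKDQEILYEQLAKKVMKVLEKQLGISEEEARRAKQVKFVVYFKDGSSTEIDGSSDEHEENKINAAEIKKIEVKVD
>design_05 IgE FG-loop display design on the 1YN3 EAP scaffold
GVTVPFTVTHPHLPRALKSELTFKKDQEILFEHLAAEVKRVLEEKQGITEEEAKRAKQVKFVVYFKDGSSKEIDGSSSEHEQRKINAAEIKKIEVKID
>design_06 IgE FG-loop display design on the 1YN3 EAP scaffold
GTKVPYEVTHPHLPRALHSHLEFEKDKEILFEHLAKKVKEVLKKERGISEEEARRAKQVKFVVYFKDGSSQEIDGSSDESKDNKINAAEIKKISVNVD
>design_07 IgE FG-loop display design on the 1YN3 EAP scaffold
GTHVPFTVTHPHLPRALSDHLEYEKDKRVLLEEIAKKVKEVLKKKRGISEEEARRAKQVSFIIFFKDGSSKKVDGSSDESKRDEVDAAKIKKIEINVD
>design_08 IgE FG-loop display design on the 1YN3 EAP scaffold
GTRVPFKVTHPHLPRALESELEFEKDKEILFEELAKKVKEMAKKQRGISEEEARRAKQFKFIVYFKDGSSQEIDGKSDESEDNKINAAEIKKIEVHVD
>design_09 IgE FG-loop display design on the 1YN3 EAP scaffold
GTTVPFTVTHPHLPRALSSELEFEKDKEILFEELLKKVKEMLKKQRGISEEEARRAKQVKFIVYFKDGSSQEIDGSSDEHKENKINAAEIKKIEVHVD
>design_10 IgE FG-loop display design on the 1YN3 EAP scaffold
GTTVPFHVTHPHLPRALQSELEFEKDKEILLEHLAKKVKEVLKKQRGISEEEAKRAKQVKFVVYFKDGSSKEVDGSSEESEDDKINAAEIKKISVNVD
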