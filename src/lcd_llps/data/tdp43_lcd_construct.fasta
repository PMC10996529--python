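>TDP43_LCD_construct thrombin-cleaved construct: GS + TDP-43 residues 266-414; tdp43_offset=263; md5=70db8d609b3f5254535102898545a0f0
GSSNRQLERSGRFGGNPGGFGNQGGFGNSRGGGAGLGNNQGSNMGGGMNFGAFSINPAMM
AAAQAALQSSWGMMGMLASQQNQSGPSGNNQNQGNMQREPNQAFGSGNNSYSGSNSGAAI
GWGSASNAGSGSGFNGGFGSSMDSKSSGWGM
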