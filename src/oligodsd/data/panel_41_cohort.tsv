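symbol	aliases	categories	tags	inheritance	diagnostic_panel_member	source_note
ATF3		XX_DSD_reported|XY_DSD_reported|gonadal_expression	female_gonadal|hypospadias|other_dsd	unknown	1	hypospadias; female gonadal development
BNC2		XY_DSD_reported|gonadal_expression	cryptorchidism|hypospadias|micropenis|other_dsd	unknown	1	hypospadias; gonadal development
CDH23		gonadal_expression	other_dsd	AD_AR	0	gonadal development candidate
COL9A3		gonadal_expression	other_dsd	AD	0	male gonadal development
CUL4B		XY_DSD_reported		XL	1	abnormal genitourinary system; X-linked
CYP1A1		XY_DSD_reported|syndromic	hypospadias|syndromic_genitourinary	AR	0	association with hypospadias
DAPK1		XX_DSD_reported|gonadal_expression	female_gonadal|other_dsd	unknown	0	female gonadal development candidate
EMX2		XX_DSD_reported|XY_DSD_reported|gonadal_expression	female_gonadal|hypospadias|other_dsd	unknown	0	46,XX DSD; sex determination
EVC		XY_DSD_reported|gonadal_expression|syndromic	micropenis|other_dsd|syndromic_genitourinary	AR	1	Ellis-van Creveld syndrome; micropenis; gonadal development
EYA1		XY_DSD_reported|gonadal_expression	hypospadias|other_dsd	AD	0	hypospadias association; male gonadal development
FGF10		XY_DSD_reported	hypospadias|micropenis	AD	0	hypospadias risk; glans penis development
FLNA		XX_DSD_reported|XY_DSD_reported|gonadal_expression	cryptorchidism|female_gonadal|hypospadias|other_dsd	XL	1	hypospadias and cryptorchidism; androgen receptor interaction
FRAS1		XX_DSD_reported|gonadal_expression|syndromic	female_gonadal|other_dsd|syndromic_genitourinary	AR	1	Fraser syndrome; abnormal genitourinary system
FREM2		XX_DSD_reported|gonadal_expression	female_gonadal|other_dsd	AR	1	Fraser syndrome; abnormal genitalia
GLI2		XY_DSD_reported|gonadal_expression	hypospadias|other_dsd	AD	0	hypospadias risk; male gonadal development
GLI3		XX_DSD_reported|XY_DSD_reported|gonadal_expression	female_gonadal|hypospadias|other_dsd	AD	1	hypospadias risk; early genital primordia
GRID1		XY_DSD_reported	hypospadias	unknown	0	candidate for hypospadias
HOXA13		XY_DSD_reported|gonadal_expression|syndromic	hypospadias|other_dsd|syndromic_genitourinary	AD	1	hand-foot-genital syndrome; hypospadias
HSD3B2		XY_DSD_reported	hypospadias	AR	1	hypospadias; steroid hormone synthesis
IGFBP2		XX_DSD_reported|gonadal_expression	female_gonadal|other_dsd	unknown	0	ovary development candidate
IRX5		XX_DSD_reported|XY_DSD_reported|gonadal_expression	female_gonadal|hypospadias|other_dsd	AR	1	hypospadias association; female gonadal development
IRX6		XY_DSD_reported	hypospadias	unknown	0	hypospadias association
MAML1		mamld1_related		unknown	0	MAMLD1-related transcriptional coactivator
MAML2		mamld1_related		unknown	0	MAMLD1-related transcriptional coactivator
MAML3		XX_DSD_reported|gonadal_expression|mamld1_related	female_gonadal|other_dsd	unknown	0	MAMLD1-related; female gonadal development network
MYO7A		gonadal_expression	other_dsd	AD_AR	0	male gonadal development candidate
NOTCH1		gonadal_expression	other_dsd	AD	0	related to SHH and FGF10 signaling
NOTCH2		gonadal_expression	other_dsd	AD	1	primary ovarian failure; male gonadal development
NRP1		XY_DSD_reported|gonadal_expression	cryptorchidism|other_dsd	unknown	0	DSD candidate; gonadal development
PIK3R3		XX_DSD_reported|gonadal_expression	female_gonadal|other_dsd	unknown	0	female gonadal development candidate
PPARGC1B		XY_DSD_reported	hypospadias	AD_AR	0	candidate for hypospadias
PROP1		XY_DSD_reported		AR	1	pituitary hormone deficiency; hypogonadotropic hypogonadism
PTPN11		XY_DSD_reported|syndromic	cryptorchidism|syndromic_genitourinary	AD	1	Noonan syndrome; cryptorchidism
RECQL4		XY_DSD_reported|syndromic	cryptorchidism|syndromic_genitourinary	AR	1	Rothmund-Thomson syndrome; hypospadias
RET		XY_DSD_reported|gonadal_expression|syndromic	cryptorchidism|other_dsd|syndromic_genitourinary	AD	1	CAKUT syndrome; cryptorchidism; gonadal development
RIPK4		XY_DSD_reported|gonadal_expression|syndromic	cryptorchidism|micropenis|other_dsd|syndromic_genitourinary	AR	1	popliteal pterygium syndrome; genital hypoplasia; micropenis
TGFBI		gonadal_expression	other_dsd	AD	0	gonadal development candidate
WDR11		XY_DSD_reported	hypospadias	AD	1	hypospadias; small testes
WNT9A		XX_DSD_reported|gonadal_expression	female_gonadal|other_dsd	unknown	0	female gonadal development
WNT9B		XX_DSD_reported|gonadal_expression	female_gonadal|other_dsd	unknown	0	Mayer-Rokitansky-Kuster-Hauser syndrome; urogenital organogenesis
ZBTB16		XY_DSD_reported|syndromic	cryptorchidism|micropenis|syndromic_genitourinary	AR	1	11q23 deletion syndrome; cryptorchidism and micropenis
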