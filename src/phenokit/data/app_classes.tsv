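# Default app -> behavioral-class mapping (tab separated).
# Apps not listed here are classified as android_systems.
com.whatsapp	social_messenger
org.telegram.messenger	social_messenger
com.facebook.orca	social_messenger
sg.app.chat	social_messenger
com.facebook.katana	social_media
com.instagram.android	social_media
com.twitter.android	social_media
sg.app.feed	social_media
com.google.android.youtube	entertainment
com.netflix.mediaclient	entertainment
com.spotify.music	entertainment
sg.app.video	entertainment
sg.app.music	entertainment
sg.app.stream	entertainment
com.google.android.apps.maps	map_navigation
com.sg.busarrival	map_navigation
sg.app.maps	map_navigation
com.android.chrome	utility_tools
com.google.android.calendar	utility_tools
com.android.calculator2	utility_tools
sg.app.bank	utility_tools
sg.app.mail	utility_tools
sg.app.notes	utility_tools
sg.app.browser	utility_tools
sg.app.shop	utility_tools
com.king.candycrushsaga	games
com.supercell.clashofclans	games
sg.app.puzzle	games
sg.app.arcade	games
com.android.systemui	android_systems
com.android.settings	android_systems
sg.vendor.launcher	android_systems
sg.vendor.cleaner	android_systems
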